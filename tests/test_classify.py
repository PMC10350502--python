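"""Event, spike-time and rank-order digit classification."""

import json
import math

import numpy as np
import pytest

from microspike import (
    Codebook,
    DigitFont,
    DigitImage,
    FieldTuning,
    build_codebook,
    classify_event,
    classify_rank,
    classify_spiketime,
    default_event_bank,
    event_code,
    min_field_subset,
    rank_code,
    search_delays,
    spiketime_code,
)
from microspike.classify import (
    RANK_DELAYS,
    RANK_FIELDS,
    SPIKETIME_TUNING,
    stamp_origin,
)


@pytest.fixture(scope="module")
def event_book(font, params):
    return build_codebook("event", font, params=params)


@pytest.fixture(scope="module")
def spiketime_book(font, params):
    return build_codebook("spiketime", font, params=params)


@pytest.fixture(scope="module")
def rank_book(font, params):
    return build_codebook("rank", font, params=params)


class TestEventBank:
    def test_bank_has_ten_units(self):
        bank = default_event_bank()
        assert len(bank) == 10
        intents = [u.intent for u in bank]
        assert intents.count("111") == 5
        assert intents.count("1111") == 3
        assert intents.count("10111") == 2

    def test_every_unit_realises_its_intent(self, params):
        bank = default_event_bank(validate=True, params=params)
        assert all(u.validate(params) for u in bank)

    def test_single_marker_variant(self):
        bank = default_event_bank(marker_fields=("V4",))
        assert len(bank) == 9


class TestEventCoding:
    def test_all_digits_classified(self, font, params, event_book):
        assert event_book.unique
        for d, img in font.items():
            assert classify_event(img, event_book.bank, event_book, params) == d

    def test_mirror_digits_differ_only_in_asymmetry_units(self, font, params, event_book):
        # positions 5..9 are the c=5.0 units on V2/V3/V4 (4-run + marker);
        # the mirror pair 2/5 must agree on every symmetric (c=6) unit
        c2, c5 = event_book.entries[2], event_book.entries[5]
        diff = {i for i in range(10) if c2[i] != c5[i]}
        assert diff
        assert diff <= {5, 6, 7, 8, 9}
        assert all(c2[i] == c5[i] for i in range(5))

    def test_blank_image_maps_to_empty_code(self, font, params, event_book):
        blank = DigitImage(np.zeros((5, 5), dtype=int))
        code = event_code(blank, event_book.bank, params)
        assert code == (0,) * 10
        pred = classify_event(blank, event_book.bank, event_book, params)
        empty_digits = [d for d, c in event_book.entries.items() if c == code]
        assert pred == (empty_digits[0] if len(empty_digits) == 1 else None)
        # with empty codes outlawed, a blank is always unknown
        strict = Codebook("event", event_book.entries, bank=event_book.bank,
                          allow_empty_code=False)
        assert classify_event(blank, event_book.bank, strict, params) is None

    def test_codes_are_deterministic(self, font, params, event_book):
        img = font[3]
        a = event_code(img, event_book.bank, params)
        b = event_code(img, event_book.bank, params)
        assert a == b


class TestSpikeTime:
    def test_codebook_unique_and_correct(self, font, params, spiketime_book):
        assert spiketime_book.unique
        for d, img in font.items():
            assert classify_spiketime(img, spiketime_book, params) == d

    def test_silent_field_stamps_zero(self, font, params, spiketime_book):
        blank = DigitImage(np.zeros((5, 5), dtype=int))
        code = spiketime_code(
            blank, spiketime_book.fields, spiketime_book.stamp_origin,
            spiketime_book.tuning, params,
        )
        assert code == (0,) * len(spiketime_book.fields)

    def test_four_runs_stamp_before_three_runs(self, params, font):
        # delta_tau > tau_b at the read-out tuning: a 4-run always lands
        # in an earlier window than a 3-run starting at the same bit
        t_min = stamp_origin(font, RANK_FIELDS, SPIKETIME_TUNING, params)
        img4 = DigitImage.from_strings(["01000", "01000", "01000", "01000", "00000"])
        img3 = DigitImage.from_strings(["01000", "01000", "01000", "00000", "00000"])
        s4 = spiketime_code(img4, ("V2",), t_min, SPIKETIME_TUNING, params)
        s3 = spiketime_code(img3, ("V2",), t_min, SPIKETIME_TUNING, params)
        assert 0 < s4[0] < s3[0]

    def test_stamp_classes_do_not_overlap(self, font, params):
        # distinct (pattern kind, position) features never share a stamp:
        # shifting a 3-run by one bit moves it a full window later
        t_min = stamp_origin(font, RANK_FIELDS, SPIKETIME_TUNING, params)
        stamps = []
        for rows in (
            ["01000", "01000", "01000", "00000", "00000"],  # 3-run rows 1-3
            ["00000", "01000", "01000", "01000", "00000"],  # 3-run rows 2-4
        ):
            img = DigitImage.from_strings(rows)
            stamps.append(
                spiketime_code(img, ("V2",), t_min, SPIKETIME_TUNING, params)[0]
            )
        assert stamps[0] != stamps[1]


class TestRankOrder:
    def test_codebook_unique_and_correct(self, font, params, rank_book):
        assert rank_book.unique
        assert rank_book.delays == tuple(RANK_DELAYS)
        for d, img in font.items():
            assert classify_rank(img, rank_book, params) == d

    def test_codes_are_at_most_three_fields(self, rank_book):
        for code in rank_book.entries.values():
            assert len(code) <= 3
            assert len(set(code)) == len(code)

    def test_digits_with_few_spikes_still_decode(self, font, params, rank_book):
        short = [d for d, c in rank_book.entries.items() if len(c) < 3]
        assert short  # the font contains sparse digits
        for d in short:
            assert classify_rank(font[d], rank_book, params) == d

    def test_global_delay_shift_preserves_codes(self, font, params, rank_book):
        shifted = [d + 200 for d in RANK_DELAYS]
        book2 = build_codebook("rank", font, delays=shifted, params=params)
        assert book2.entries == rank_book.entries

    def test_paper_delay_vector_found_valid_by_search(self, font, params):
        good = search_delays(
            font, n_trials=1, seed=7, include=[RANK_DELAYS], params=params
        )
        assert tuple(RANK_DELAYS) in good

    def test_random_delay_vectors_often_work(self, font, params):
        # delays are cheap hyperparameters: a seeded draw of a few
        # vectors from [1, 100] contains at least one unique codebook
        good = search_delays(font, n_trials=6, seed=123, params=params)
        assert len(good) >= 1


class TestCodebookObject:
    def test_permuting_fields_preserves_uniqueness(self, spiketime_book):
        perm = list(reversed(range(len(spiketime_book.fields))))
        entries = {
            d: tuple(code[i] for i in perm)
            for d, code in spiketime_book.entries.items()
        }
        book = Codebook("spiketime", entries,
                        fields=tuple(spiketime_book.fields[i] for i in perm))
        assert book.unique == spiketime_book.unique

    def test_duplicate_entries_clear_unique_flag(self, font):
        entries = {d: (1, 2, 3) for d in range(10)}
        book = Codebook("event", entries)
        assert not book.unique
        assert book.decode((1, 2, 3)) is None  # ambiguous

    def test_json_round_trip(self, tmp_path, event_book, spiketime_book, rank_book):
        for book in (event_book, spiketime_book, rank_book):
            path = tmp_path / f"{book.scheme}.json"
            book.save(path)
            again = Codebook.load(path)
            assert again.entries == book.entries
            assert again.fields == tuple(book.fields)
            assert again.unique == book.unique
            assert again.delays == tuple(book.delays)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            Codebook("fourier", {})


class TestMinFieldSubset:
    def test_toy_font_needs_single_field(self, params):
        # two images separable by V2 alone (4-run vs silent column)
        rows_a = ["01000", "01000", "01000", "01000", "00000"]
        rows_b = ["00000", "00000", "00000", "00000", "00000"]
        sub, size = min_field_subset(
            "spiketime",
            _TwoDigitFont(
                DigitImage.from_strings(rows_a), DigitImage.from_strings(rows_b)
            ),
            candidate_fields=("V2", "V3"),
            params=params,
        )
        assert size == 1
        assert sub == ("V2",)

    def test_matches_exhaustive_oracle(self, font, params, spiketime_book):
        # brute-force over every subset, no size-ordered shortcut
        from itertools import combinations

        fields = tuple(spiketime_book.fields)
        t_min = spiketime_book.stamp_origin
        full = {
            d: spiketime_code(img, fields, t_min, spiketime_book.tuning, params)
            for d, img in font.items()
        }
        best = None
        for r in range(1, len(fields) + 1):
            for idx in combinations(range(len(fields)), r):
                codes = {d: tuple(full[d][i] for i in idx) for d in full}
                if len(set(codes.values())) == len(codes):
                    if best is None or r < best:
                        best = r
            if best is not None:
                break
        sub, size = min_field_subset(
            "spiketime", font, candidate_fields=fields, params=params
        )
        assert size == best

    def test_unseparable_candidates_rejected(self, font, params):
        with pytest.raises(ValueError):
            min_field_subset(
                "spiketime", font, candidate_fields=("H2",), params=params
            )


class _TwoDigitFont:
    """Minimal font stand-in exposing .items() for subset searches."""

    def __init__(self, *images):
        self._images = dict(enumerate(images))

    def items(self):
        return self._images.items()
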