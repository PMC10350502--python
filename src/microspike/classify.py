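"""Spike-based digit classification: event, spike-time and rank-order codes.

Three online read-out schemes turn the responses of receptive-field
neurons into digit labels:

* **event coding** - a bank of detector neurons, each tuned to fire on a
  specific feature ("111", "1111", or the asymmetric "10111") in one
  receptive field; the binary fire/no-fire vector is the code.
* **spike-time coding** - one neuron per receptive field, biased close
  to the excitable threshold so that the first-spike latency separates
  3-run from 4-run features by more than one bit time; each field
  contributes a discrete temporal stamp k in 1..5 (0 = no spike).
* **rank-order coding** - the same fields with per-field onset delays;
  only the identity order of the first (up to) three spikes is kept.

Codebooks map each digit of the reference font to its code; decoding is
an exact lookup.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .coding import DigitFont, DigitImage, image_to_fields
from .maps import (
    min_run_to_spike,
    pattern_discriminates,
    latency_difference,
    simulate_bits,
)
from .model import LaserParams

__all__ = [
    "FieldTuning",
    "DetectorSpec",
    "Codebook",
    "EVENT_RUN3_TUNING",
    "EVENT_RUN4_TUNING",
    "EVENT_MARKER_TUNING",
    "SPIKETIME_TUNING",
    "RANK_TUNING",
    "RANK_FIELDS",
    "RANK_DELAYS",
    "default_event_bank",
    "event_code",
    "classify_event",
    "spiketime_code",
    "classify_spiketime",
    "rank_code",
    "classify_rank",
    "build_codebook",
    "min_field_subset",
    "search_delays",
]


@dataclass(frozen=True)
class FieldTuning:
    """Operating point of a receptive-field neuron."""

    mu0: float
    c: float
    tau_b: float = 50.0
    tau_p: float = 30.0


# Detector operating points.  The "111" detector sits deep in the
# excitable regime where only >= 3 consecutive pulses summate to a spike.
# The "1111"/"10111" amplitude lies in the band where 4-runs (and the
# head-started 10111) fire but a bare 3-run and its mirror 11101 do not;
# the band is located by the build-time intent checks below, which keep
# the bank valid for the implemented dynamics.
EVENT_RUN3_TUNING = FieldTuning(mu0=1.25, c=6.0)
EVENT_RUN4_TUNING = FieldTuning(mu0=1.25, c=5.0)
EVENT_MARKER_TUNING = FieldTuning(mu0=1.25, c=5.0)

# Spike-time read-out: biased near the excitable threshold so that the
# 3-run/4-run latency gap exceeds one bit time and maps to distinct
# temporal stamps (delta_tau ~ 180 at this point, > 3 bit times).
SPIKETIME_TUNING = FieldTuning(mu0=2.65, c=0.36)

# Rank-order read-out: slightly stronger drive, so every >= 3-run feature
# fires with a pattern-dependent latency; identity order does the rest.
RANK_TUNING = FieldTuning(mu0=2.6, c=0.7)
RANK_FIELDS: tuple[str, ...] = ("V2", "V3", "V4", "H1", "H3", "H4", "H5")
#: Per-field onset delays (hyperparameters breaking arrival degeneracies).
RANK_DELAYS: tuple[int, ...] = (24, 47, 20, 60, 91, 9, 67)

#: Arrivals closer than this are considered simultaneous (tie).
TIE_TOLERANCE = 0.5

#: Stamp labels run 1..5 (bins of width tau_b); 0 encodes "no spike".
N_STAMPS = 5


@dataclass(frozen=True)
class DetectorSpec:
    """One event-coding unit: a receptive field plus a tuned neuron.

    ``intent`` is the feature the unit is meant to detect; ``validate``
    checks the tuning actually realises it under the model dynamics.
    """

    field: str
    intent: str
    tuning: FieldTuning

    def __post_init__(self) -> None:
        if self.intent not in ("111", "1111", "10111"):
            raise ValueError(f"unsupported intent {self.intent!r}")

    def validate(self, params: LaserParams = LaserParams()) -> bool:
        t = self.tuning
        if self.intent == "111":
            return min_run_to_spike(params, t.mu0, t.c, t.tau_b, t.tau_p) == 3
        if self.intent == "1111":
            return min_run_to_spike(params, t.mu0, t.c, t.tau_b, t.tau_p) == 4
        return pattern_discriminates(
            params, t.mu0, t.c, "10111", "11101", t.tau_b, t.tau_p
        )

    def fires(self, bits, params: LaserParams = LaserParams()) -> bool:
        t = self.tuning
        return simulate_bits(bits, t.mu0, t.c, t.tau_b, t.tau_p, params=params).n_spikes > 0


def default_event_bank(
    marker_fields: Sequence[str] = ("V2", "V4"),
    validate: bool = False,
    params: LaserParams = LaserParams(),
) -> list[DetectorSpec]:
    """The 10-unit detector bank for event-coded digit classification.

    Five "111" units on {H1, H3, H5, V2, V4}, three "1111" units on
    {V2, V3, V4} and asymmetry ("10111") units on ``marker_fields``
    (both V2 and V4 by default, for a 10-unit bank; passing a single
    field selects the smaller 9-unit variant).
    """
    bank = [DetectorSpec(f, "111", EVENT_RUN3_TUNING) for f in ("H1", "H3", "H5", "V2", "V4")]
    bank += [DetectorSpec(f, "1111", EVENT_RUN4_TUNING) for f in ("V2", "V3", "V4")]
    bank += [DetectorSpec(f, "10111", EVENT_MARKER_TUNING) for f in marker_fields]
    if validate:
        bad = [u for u in bank if not u.validate(params)]
        if bad:
            raise ValueError(f"detector tunings do not realise their intents: {bad}")
    return bank


# ---------------------------------------------------------------------------
# Event coding
# ---------------------------------------------------------------------------


def event_code(
    img: DigitImage,
    bank: Sequence[DetectorSpec],
    params: LaserParams = LaserParams(),
) -> tuple[int, ...]:
    """Fire/no-fire bit per bank unit, in bank order."""
    fields = image_to_fields(img)
    return tuple(int(u.fires(fields[u.field].bits, params)) for u in bank)


def classify_event(
    img: DigitImage,
    bank: Sequence[DetectorSpec],
    codebook: "Codebook",
    params: LaserParams = LaserParams(),
) -> int | None:
    """Decode an image through the event codebook; None when no code matches."""
    return codebook.decode(event_code(img, bank, params))


# ---------------------------------------------------------------------------
# Spike-time (temporal stamp) coding
# ---------------------------------------------------------------------------


def _field_latency(
    bits, tuning: FieldTuning, params: LaserParams, tau_d: float = 0.0
) -> float:
    # The system is autonomous and starts from its steady state, so a
    # delayed program's spike time is exactly tau_d plus the undelayed
    # one; simulating at tau_d = 0 lets the memoised solution be shared
    # across delay vectors.
    spikes = simulate_bits(
        bits, tuning.mu0, tuning.c, tuning.tau_b, tuning.tau_p, params=params,
    )
    return tau_d + spikes.first_spike_time


def stamp_origin(
    font: DigitFont,
    fields: Sequence[str],
    tuning: FieldTuning = SPIKETIME_TUNING,
    params: LaserParams = LaserParams(),
) -> float:
    """Smallest first-spike time over the font and field set (stamp reference)."""
    best = math.inf
    for _, img in font.items():
        f = image_to_fields(img)
        for name in fields:
            best = min(best, _field_latency(f[name].bits, tuning, params))
    if not math.isfinite(best):
        raise ValueError("no field of the font spikes at this tuning")
    return best


def spiketime_code(
    img: DigitImage,
    fields: Sequence[str],
    t_min: float,
    tuning: FieldTuning = SPIKETIME_TUNING,
    params: LaserParams = LaserParams(),
) -> tuple[int, ...]:
    """Temporal-stamp code: per field, k = 1..5 (bin of width tau_b), 0 = silent.

    Stamps are bin indices of the first-spike time in consecutive
    ``tau_b``-wide windows anchored at ``t_min`` (the earliest spike
    observed over the reference font, stored in the codebook).
    """
    f = image_to_fields(img)
    code = []
    for name in fields:
        t = _field_latency(f[name].bits, tuning, params)
        if math.isfinite(t):
            k = int(math.floor((t - t_min) / tuning.tau_b)) + 1
            code.append(min(N_STAMPS, max(1, k)))
        else:
            code.append(0)
    return tuple(code)


def classify_spiketime(
    img: DigitImage,
    codebook: "Codebook",
    params: LaserParams = LaserParams(),
) -> int | None:
    code = spiketime_code(
        img, codebook.fields, codebook.stamp_origin, codebook.tuning, params
    )
    return codebook.decode(code)


# ---------------------------------------------------------------------------
# Rank-order coding
# ---------------------------------------------------------------------------


def rank_code(
    img: DigitImage,
    fields: Sequence[str] = RANK_FIELDS,
    delays: Sequence[float] = RANK_DELAYS,
    tuning: FieldTuning = RANK_TUNING,
    params: LaserParams = LaserParams(),
    tie_tolerance: float = TIE_TOLERANCE,
) -> tuple[tuple[str, ...], bool]:
    """Identity order of the first <= 3 fields to spike, plus a tie flag.

    Each field's pump program is onset-delayed by its own tau_d, so the
    arrival time is delay + pattern latency.  Arrivals closer than
    ``tie_tolerance`` are flagged and broken deterministically by field
    declaration order.
    """
    if len(delays) != len(fields):
        raise ValueError("need one delay per field")
    f = image_to_fields(img)
    arrivals = []
    for pos, (name, d) in enumerate(zip(fields, delays)):
        t = _field_latency(f[name].bits, tuning, params, tau_d=float(d))
        if math.isfinite(t):
            arrivals.append((t, pos, name))
    arrivals.sort()
    tie = any(
        b[0] - a[0] < tie_tolerance for a, b in zip(arrivals[:-1], arrivals[1:])
    )
    if tie:
        warnings.warn(
            "near-simultaneous spike arrivals; order broken by field position",
            stacklevel=2,
        )
    return tuple(name for _, _, name in arrivals[:3]), tie


def classify_rank(
    img: DigitImage,
    codebook: "Codebook",
    params: LaserParams = LaserParams(),
) -> int | None:
    code, _ = rank_code(
        img, codebook.fields, codebook.delays, codebook.tuning, params
    )
    return codebook.decode(code)


# ---------------------------------------------------------------------------
# Codebooks
# ---------------------------------------------------------------------------


@dataclass
class Codebook:
    """Digit -> code lookup table for one coding scheme.

    ``unique`` records whether the entries are pairwise distinct (exact
    decoding is only well defined in that case; non-unique codebooks are
    valid objects that decode ambiguous codes to None).
    """

    scheme: str
    entries: dict[int, tuple]
    fields: tuple[str, ...] = ()
    tuning: FieldTuning | None = None
    bank: tuple[DetectorSpec, ...] = ()
    delays: tuple[float, ...] = ()
    stamp_origin: float | None = None
    allow_empty_code: bool = True

    def __post_init__(self) -> None:
        if self.scheme not in ("event", "spiketime", "rank"):
            raise ValueError(f"unknown scheme {self.scheme!r}")

    @property
    def unique(self) -> bool:
        codes = list(self.entries.values())
        return len(set(codes)) == len(codes)

    def decode(self, code: tuple) -> int | None:
        """Exact-match lookup; None for unknown or ambiguous codes."""
        if not self.allow_empty_code and not any(code):
            return None
        matches = [d for d, c in self.entries.items() if c == tuple(code)]
        return matches[0] if len(matches) == 1 else None

    # -- serialisation ----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "scheme": self.scheme,
            "entries": {str(d): list(c) for d, c in self.entries.items()},
            "fields": list(self.fields),
            "tuning": asdict(self.tuning) if self.tuning else None,
            "bank": [
                {"field": u.field, "intent": u.intent, "tuning": asdict(u.tuning)}
                for u in self.bank
            ],
            "delays": list(self.delays),
            "stamp_origin": self.stamp_origin,
            "allow_empty_code": self.allow_empty_code,
            "unique": self.unique,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Codebook":
        d = json.loads(text)

        def as_code(c):
            return tuple(tuple(x) if isinstance(x, list) else x for x in c)

        return cls(
            scheme=d["scheme"],
            entries={int(k): as_code(v) for k, v in d["entries"].items()},
            fields=tuple(d.get("fields") or ()),
            tuning=FieldTuning(**d["tuning"]) if d.get("tuning") else None,
            bank=tuple(
                DetectorSpec(u["field"], u["intent"], FieldTuning(**u["tuning"]))
                for u in d.get("bank") or ()
            ),
            delays=tuple(d.get("delays") or ()),
            stamp_origin=d.get("stamp_origin"),
            allow_empty_code=d.get("allow_empty_code", True),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "Codebook":
        with open(path) as fh:
            return cls.from_json(fh.read())


def build_codebook(
    scheme: str,
    font: DigitFont,
    bank: Sequence[DetectorSpec] | None = None,
    fields: Sequence[str] | None = None,
    tuning: FieldTuning | None = None,
    delays: Sequence[float] | None = None,
    params: LaserParams = LaserParams(),
    allow_empty_code: bool = True,
) -> Codebook:
    """Simulate every font digit under a scheme and collect its codes."""
    if scheme == "event":
        bank = tuple(bank if bank is not None else default_event_bank())
        entries = {d: event_code(img, bank, params) for d, img in font.items()}
        return Codebook(
            "event", entries, bank=bank, allow_empty_code=allow_empty_code
        )
    if scheme == "spiketime":
        fields = tuple(fields if fields is not None else RANK_FIELDS)
        tuning = tuning or SPIKETIME_TUNING
        t_min = stamp_origin(font, fields, tuning, params)
        entries = {
            d: spiketime_code(img, fields, t_min, tuning, params)
            for d, img in font.items()
        }
        return Codebook(
            "spiketime", entries, fields=fields, tuning=tuning, stamp_origin=t_min
        )
    if scheme == "rank":
        fields = tuple(fields if fields is not None else RANK_FIELDS)
        tuning = tuning or RANK_TUNING
        delays = tuple(delays if delays is not None else RANK_DELAYS)
        entries = {
            d: rank_code(img, fields, delays, tuning, params)[0]
            for d, img in font.items()
        }
        return Codebook("rank", entries, fields=fields, tuning=tuning, delays=delays)
    raise ValueError(f"unknown scheme {scheme!r}")


# ---------------------------------------------------------------------------
# Minimal field subsets and delay search
# ---------------------------------------------------------------------------


ALL_FIELDS: tuple[str, ...] = ("H1", "H2", "H3", "H4", "H5", "V1", "V2", "V3", "V4", "V5")


def min_field_subset(
    scheme: str,
    font: DigitFont,
    candidate_fields: Sequence[str] = ALL_FIELDS,
    tuning: FieldTuning | None = None,
    delays: Sequence[float] | None = None,
    params: LaserParams = LaserParams(),
) -> tuple[tuple[str, ...], int]:
    """Smallest field subset whose per-digit codes are pairwise distinct.

    Per-field codes are computed once over ``candidate_fields`` (spike
    times are memoised, so the exhaustive size-ordered subset scan costs
    at most 2**n cheap tuple comparisons).  Raises if even the full
    candidate set is non-unique.
    """
    candidate_fields = tuple(candidate_fields)
    if scheme == "spiketime":
        tuning = tuning or SPIKETIME_TUNING
        t_min = stamp_origin(font, candidate_fields, tuning, params)
        full = {
            d: spiketime_code(img, candidate_fields, t_min, tuning, params)
            for d, img in font.items()
        }
    elif scheme == "event":
        bank = [DetectorSpec(f, "111", tuning or EVENT_RUN3_TUNING) for f in candidate_fields]
        full = {d: event_code(img, bank, params) for d, img in font.items()}
    else:
        raise ValueError("subset search supports 'event' and 'spiketime'")

    digits = sorted(full)
    if len({full[d] for d in digits}) < len(digits):
        raise ValueError("full candidate field set does not yield unique codes")

    for size in range(1, len(candidate_fields) + 1):
        for idx in combinations(range(len(candidate_fields)), size):
            sub = {d: tuple(full[d][i] for i in idx) for d in digits}
            if len({sub[d] for d in digits}) == len(digits):
                return tuple(candidate_fields[i] for i in idx), size
    raise AssertionError("unreachable: full set is unique")


def search_delays(
    font: DigitFont,
    fields: Sequence[str] = RANK_FIELDS,
    tuning: FieldTuning = RANK_TUNING,
    n_trials: int = 100,
    seed: int = 0,
    delay_range: tuple[int, int] = (1, 100),
    include: Sequence[Sequence[float]] = (),
    params: LaserParams = LaserParams(),
) -> list[tuple[int, ...]]:
    """Sample random per-field delay vectors; keep those with unique rank codes.

    Delays are integers drawn uniformly from ``delay_range`` (inclusive)
    with a seeded generator, so results are reproducible.  Vectors in
    ``include`` are checked first.  Tie-flagged codebooks are rejected.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = delay_range
    trials = [tuple(int(x) for x in v) for v in include]
    trials += [
        tuple(int(x) for x in rng.integers(lo, hi + 1, size=len(fields)))
        for _ in range(n_trials)
    ]
    good: list[tuple[int, ...]] = []
    for delays in trials:
        entries = {}
        tie_seen = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for d, img in font.items():
                code, tie = rank_code(img, fields, delays, tuning, params)
                tie_seen |= tie
                entries[d] = code
        if tie_seen:
            continue
        if len(set(entries.values())) == len(entries):
            good.append(delays)
    return good
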