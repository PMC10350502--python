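"""Input coding: pump waveforms from bit sequences and image receptive fields.

A binary pixel sequence ``p_0 p_1 ...`` drives the laser through its pump::

    mu1(t) = mu0 + sum_i c * p_i * boxcar_{tau_p}(t - i*tau_b - tau_d)

i.e. every "1" bit adds a rectangular pump pulse of amplitude ``c`` and
duration ``tau_p`` inside its bit slot of duration ``tau_b >= tau_p``.
Choosing ``tau_b`` slightly below the neuron's relative refractory time
makes consecutive pulses *summate*, so the neuron fires only once a
sufficiently long run of "1"s has accumulated - this is the receptive-field
mechanism used for digit features.

Images are 5x5 binary grids; each row ``H_i`` (read left to right) and
column ``V_j`` (read top to bottom) yields one 5-bit sequence, giving ten
receptive fields per image.  The packaged digit font is a reconstructed
5x5 pixel set for the digits 0-9 satisfying the structural constraints the
classifiers rely on (see :func:`validate_font`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import DEFAULT_PADDING

__all__ = [
    "PumpProgram",
    "DigitImage",
    "ReceptiveField",
    "DigitFont",
    "FontReport",
    "encode_bits",
    "constant_pump",
    "image_to_fields",
    "field_bits",
    "validate_font",
    "load_default_font",
    "FIELD_NAMES",
]

#: Receptive-field names in canonical order: rows then columns.
FIELD_NAMES: tuple[str, ...] = (
    "H1", "H2", "H3", "H4", "H5", "V1", "V2", "V3", "V4", "V5",
)


def _coerce_bits(bits) -> tuple[int, ...]:
    if isinstance(bits, str):
        seq = [c for c in bits if not c.isspace()]
    else:
        seq = list(bits)
    out = []
    for b in seq:
        v = int(b)
        if v not in (0, 1):
            raise ValueError(f"bits must be 0/1, got {b!r}")
        out.append(v)
    if not out:
        raise ValueError("bit sequence must be non-empty")
    return tuple(out)


@dataclass(frozen=True)
class PumpProgram:
    """A pump waveform defined by a bit sequence.

    Bit ``i`` occupies the half-open slot
    ``[i*tau_b + tau_d, i*tau_b + tau_d + tau_p)`` so that abutting pulses
    (``tau_p == tau_b``) concatenate without double counting.  ``t_pad``
    is post-sequence padding kept for integration so that late spikes
    (large latency near the excitable threshold) are still observed.
    """

    bits: tuple[int, ...]
    mu0: float
    c: float
    tau_b: float = 50.0
    tau_p: float = 30.0
    tau_d: float = 0.0
    t_pad: float = DEFAULT_PADDING

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", _coerce_bits(self.bits))
        if self.tau_p > self.tau_b:
            raise ValueError(
                f"tau_p ({self.tau_p}) must not exceed tau_b ({self.tau_b})"
            )
        if self.tau_p <= 0 or self.tau_b <= 0:
            raise ValueError("tau_b and tau_p must be positive")
        if self.c < 0:
            raise ValueError("pump amplitude c must be >= 0")
        if self.tau_d < 0:
            raise ValueError("onset delay tau_d must be >= 0")
        if self.t_pad < 0:
            raise ValueError("t_pad must be >= 0")

    # -- geometry ---------------------------------------------------------
    @property
    def n_bits(self) -> int:
        return len(self.bits)

    @property
    def onset(self) -> float:
        """Time of the first bit slot (latency reference)."""
        return self.tau_d

    @property
    def end_of_bits(self) -> float:
        return self.tau_d + self.n_bits * self.tau_b

    @property
    def total_time(self) -> float:
        return self.end_of_bits + self.t_pad

    def pulse_intervals(self) -> list[tuple[float, float]]:
        """[start, end) intervals of the "1"-bit pump pulses."""
        return [
            (i * self.tau_b + self.tau_d, i * self.tau_b + self.tau_d + self.tau_p)
            for i, p in enumerate(self.bits)
            if p
        ]

    # -- evaluation -------------------------------------------------------
    def mu1_scalar(self, t: float) -> float:
        for a, b in self.pulse_intervals():
            if a <= t < b:
                return self.mu0 + self.c
        return self.mu0

    def mu1(self, t):
        """Vectorised waveform evaluation mu1(t)."""
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.mu0)
        for a, b in self.pulse_intervals():
            out = out + self.c * ((t >= a) & (t < b))
        return out if out.shape else float(out)

    def __call__(self, t):
        return self.mu1(t)

    def pulse_energy(self) -> float:
        """Integral of mu1 - mu0: c * tau_p * (number of 1-bits)."""
        return self.c * self.tau_p * sum(self.bits)

    def with_delay(self, tau_d: float) -> "PumpProgram":
        return PumpProgram(
            self.bits, self.mu0, self.c, self.tau_b, self.tau_p, tau_d, self.t_pad
        )

    def to_frame(self, dt: float = 1.0) -> pd.DataFrame:
        t = np.arange(0.0, self.total_time + dt / 2, dt)
        return pd.DataFrame({"t": t, "mu1": self.mu1(t)})

    def to_csv(self, path, dt: float = 1.0) -> None:
        self.to_frame(dt).to_csv(path, index=False)


def encode_bits(
    bits,
    mu0: float,
    c: float,
    tau_b: float = 50.0,
    tau_p: float = 30.0,
    tau_d: float = 0.0,
    t_pad: float = DEFAULT_PADDING,
) -> PumpProgram:
    """Build the pump waveform for a bit sequence (see module docstring)."""
    return PumpProgram(_coerce_bits(bits), mu0, c, tau_b, tau_p, tau_d, t_pad)


def constant_pump(mu0: float, horizon: float) -> PumpProgram:
    """A constant pump mu0 held for ``horizon`` time units (no input bits)."""
    if horizon <= 1.0:
        raise ValueError("horizon must exceed one time unit")
    return PumpProgram((0,), mu0, 0.0, tau_b=1.0, tau_p=1.0, t_pad=horizon - 1.0)


# ---------------------------------------------------------------------------
# Images and receptive fields
# ---------------------------------------------------------------------------


@dataclass
class DigitImage:
    """A 5x5 binary pixel image, optionally labelled with its digit."""

    pixels: np.ndarray
    label: int | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=int)
        if px.shape != (5, 5):
            raise ValueError(f"image must be 5x5, got shape {px.shape}")
        if not np.isin(px, (0, 1)).all():
            raise ValueError("pixels must be binary")
        self.pixels = px
        if self.label is not None and self.label not in range(10):
            raise ValueError(f"label must be a digit 0-9, got {self.label}")

    @classmethod
    def from_strings(cls, rows: Sequence[str], label: int | None = None):
        grid = [[int(ch) for ch in row.strip()] for row in rows]
        return cls(np.array(grid), label=label)

    def to_strings(self) -> list[str]:
        return ["".join(str(v) for v in row) for row in self.pixels]

    def transposed(self) -> "DigitImage":
        return DigitImage(self.pixels.T.copy(), label=self.label)

    def mirrored_lr(self) -> "DigitImage":
        return DigitImage(self.pixels[:, ::-1].copy(), label=self.label)


@dataclass(frozen=True)
class ReceptiveField:
    """One row (H) or column (V) of an image, read as a 5-bit sequence."""

    axis: str
    index: int
    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.axis not in ("H", "V"):
            raise ValueError("axis must be 'H' or 'V'")
        if self.index not in range(1, 6):
            raise ValueError("index must be 1..5")

    @property
    def name(self) -> str:
        return f"{self.axis}{self.index}"

    @property
    def bit_string(self) -> str:
        return "".join(str(b) for b in self.bits)


def image_to_fields(
    img: DigitImage, column_direction: str = "down"
) -> dict[str, ReceptiveField]:
    """Extract the ten receptive fields H1..H5, V1..V5 of an image.

    Rows are read left to right.  Columns are read top to bottom by
    default (``column_direction="down"``); ``"up"`` flips the column
    read-out, which swaps the roles of the mirror-symmetric digit
    patterns "10111" and "11101" (i.e. of digits 2 and 5).
    """
    if not isinstance(img, DigitImage):
        img = DigitImage(np.asarray(img))
    if column_direction not in ("down", "up"):
        raise ValueError("column_direction must be 'down' or 'up'")
    fields: dict[str, ReceptiveField] = {}
    for i in range(5):
        fields[f"H{i + 1}"] = ReceptiveField("H", i + 1, tuple(img.pixels[i, :]))
    for j in range(5):
        col = img.pixels[:, j]
        if column_direction == "up":
            col = col[::-1]
        fields[f"V{j + 1}"] = ReceptiveField("V", j + 1, tuple(col))
    return fields


def field_bits(img: DigitImage, name: str, column_direction: str = "down") -> tuple[int, ...]:
    """Bit sequence of a single named receptive field, e.g. ``"V4"``."""
    return image_to_fields(img, column_direction)[name].bits


# ---------------------------------------------------------------------------
# Digit font
# ---------------------------------------------------------------------------


@dataclass
class DigitFont:
    """Ten 5x5 digit images, keyed by digit 0-9."""

    images: dict[int, DigitImage]

    def __post_init__(self) -> None:
        if sorted(self.images) != list(range(10)):
            raise ValueError("font must contain exactly the digits 0-9")
        for d, img in self.images.items():
            if img.label is None:
                img.label = d

    def __getitem__(self, digit: int) -> DigitImage:
        return self.images[digit]

    def __iter__(self):
        return iter(sorted(self.images))

    def items(self):
        return ((d, self.images[d]) for d in sorted(self.images))

    @classmethod
    def from_text(cls, text: str) -> "DigitFont":
        """Parse the plain-text font format (see :meth:`to_text`)."""
        images: dict[int, DigitImage] = {}
        block: list[str] = []
        label: int | None = None
        for raw in text.splitlines() + [""]:
            line = raw.strip()
            if line.startswith("#"):
                continue
            if not line:
                if label is not None and block:
                    images[label] = DigitImage.from_strings(block, label=label)
                block, label = [], None
                continue
            if line.startswith("digit"):
                label = int(line.split()[1])
            elif set(line) <= {"0", "1"}:
                block.append(line)
            else:
                raise ValueError(f"unrecognised font line: {raw!r}")
        return cls(images)

    @classmethod
    def from_file(cls, path) -> "DigitFont":
        with open(path) as fh:
            return cls.from_text(fh.read())

    def to_text(self) -> str:
        chunks = []
        for d, img in self.items():
            chunks.append(f"digit {d}\n" + "\n".join(img.to_strings()))
        return "\n\n".join(chunks) + "\n"

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())


def load_default_font() -> DigitFont:
    """The packaged 5x5 digit font (synthetic reconstruction, see data file)."""
    text = resources.files("microspike").joinpath("data/digits5x5.txt").read_text()
    return DigitFont.from_text(text)


# ---------------------------------------------------------------------------
# Font validation
# ---------------------------------------------------------------------------


def _max_run(bits: Sequence[int]) -> int:
    best = cur = 0
    for b in bits:
        cur = cur + 1 if b else 0
        best = max(best, cur)
    return best


#: The two mirror-symmetric marker patterns distinguishing digits 2 and 5.
MARKER_PATTERNS = ("10111", "11101")


@dataclass
class FontReport:
    """validate_font output: violations plus a per-digit run inventory."""

    violations: list[str] = field(default_factory=list)
    run_inventory: dict[int, dict[str, int]] = field(default_factory=dict)
    marker_fields: dict[int, dict[str, str]] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_font(font: DigitFont, column_direction: str = "down") -> FontReport:
    """Check the structural constraints the digit classifiers rely on.

    (a) every digit exposes at least one receptive field containing a run
        of >= 3 consecutive "1"s (the basic temporal-summation feature);
    (b) digits 2 and 5 each contain one of the asymmetric marker patterns
        "10111" / "11101", and the markers of 2 are the bit-reversed
        markers of 5 (the two digits are mirror-related);
    (c) a per-digit inventory of maximal run lengths per field is reported.
    """
    report = FontReport()
    for d, img in font.items():
        fields = image_to_fields(img, column_direction)
        inv = {name: _max_run(rf.bits) for name, rf in fields.items()}
        report.run_inventory[d] = inv
        if max(inv.values()) < 3:
            report.violations.append(
                f"digit {d}: no receptive field with a run of >= 3 ones"
            )
        markers = {
            name: rf.bit_string
            for name, rf in fields.items()
            if rf.bit_string in MARKER_PATTERNS
        }
        report.marker_fields[d] = markers

    m2 = sorted(report.marker_fields.get(2, {}).values())
    m5 = sorted(report.marker_fields.get(5, {}).values())
    if not m2:
        report.violations.append("digit 2: no field matches 10111/11101")
    if not m5:
        report.violations.append("digit 5: no field matches 10111/11101")
    if m2 and m5:
        if sorted(s[::-1] for s in m5) != m2:
            report.violations.append(
                "digits 2 and 5 marker patterns are not mirror-related"
            )
    return report
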