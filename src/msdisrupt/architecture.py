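"""Library design descriptions: microsatellite tracts, read layout, disruption rules.

A tagged template reads, 5' to 3' on the design strand::

    UP1 . VT1 . left_flank . MS . right_flank . VT2 . UP2 [. rc(VT3) . rc(UP3)]

where UP1/UP2/UP3 are universal primers designed without cytosine (so they
survive bisulfite treatment), VT1/VT2 are random varietal tags identifying the
original template molecule, and VT3 (appended during linear amplification)
identifies a first copy.  Read 1 sequences the design strand from the UP1 end;
read 2 sequences the complementary strand from the UP3 end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def converted(seq: str) -> str:
    """Apply complete C-to-T conversion (the fully deaminated sequence)."""
    return seq.replace("C", "T")


@dataclass(frozen=True)
class MicrosatelliteDef:
    """A tandem repeat tract: unit motif and expected number of units."""

    unit: str
    expected_units: int

    def __post_init__(self) -> None:
        if not self.unit or any(b not in "ACGT" for b in self.unit):
            raise ValueError(f"invalid repeat unit {self.unit!r}")
        if self.expected_units <= 0:
            raise ValueError("expected_units must be positive")

    @property
    def expected_length_bp(self) -> int:
        return self.expected_units * len(self.unit)

    @property
    def converted_unit(self) -> str:
        """The unit after complete C-to-T conversion (equals unit iff C-free)."""
        return converted(self.unit)

    @property
    def sequence(self) -> str:
        """The intact tract sequence."""
        return self.unit * self.expected_units

    @property
    def convertible(self) -> bool:
        return "C" in self.unit


@dataclass(frozen=True)
class DisruptionThresholds:
    """Bounds defining a *sufficiently disrupted* read.

    A read is sufficiently disrupted when its tract conversion rate lies in
    [conv_low, conv_high] and its maximal residual repeat does not exceed
    mrr_max units.
    """

    conv_low: float = 0.15
    conv_high: float = 0.85
    mrr_max: int = 5

    def __post_init__(self) -> None:
        if not (0.0 <= self.conv_low < self.conv_high <= 1.0):
            raise ValueError("require 0 <= conv_low < conv_high <= 1")
        if self.mrr_max < 0:
            raise ValueError("mrr_max must be non-negative")


@dataclass(frozen=True)
class DisruptionIndices:
    """Per-read disruption measurements.

    conversion_rate is None when the inter-flank region carries no position
    informative for C-to-T conversion (e.g. a mono-A tract).
    """

    conversion_rate: float | None
    mrr_units: int


@dataclass(frozen=True)
class ReadArchitecture:
    """Segment layout every read pair is parsed against."""

    up1: str
    up2: str
    up3: str
    left_flank: str
    right_flank: str
    ms: MicrosatelliteDef
    vt1_len: int = 15
    vt2_len: int = 15
    vt3_len: int = 15
    max_primer_mismatch: int = 1
    flank_probe_len: int = 20
    mrr_mode: str = "both"  # "both" counts conversion-created runs; "residual_only" does not

    def __post_init__(self) -> None:
        for name in ("up1", "up2", "up3"):
            if "C" in getattr(self, name):
                raise ValueError(f"{name} must be cytosine-free on the design strand")
        if min(self.vt1_len, self.vt2_len, self.vt3_len) <= 0:
            raise ValueError("tag lengths must be positive")
        if not self.left_flank or not self.right_flank:
            raise ValueError("flanks must be non-empty")
        if self.mrr_mode not in ("both", "residual_only"):
            raise ValueError("mrr_mode must be 'both' or 'residual_only'")

    # ---- fixed offsets within each read (0-based half-open) ----

    @property
    def r1_vt1_start(self) -> int:
        return len(self.up1)

    @property
    def r1_flank_start(self) -> int:
        """Start of the MS-proximal (left) flank in read 1."""
        return len(self.up1) + self.vt1_len

    @property
    def r1_ms_start(self) -> int:
        return self.r1_flank_start + len(self.left_flank)

    @property
    def r2_vt3_start(self) -> int:
        return len(self.up3)

    @property
    def r2_up2_start(self) -> int:
        return len(self.up3) + self.vt3_len

    @property
    def r2_vt2_start(self) -> int:
        return self.r2_up2_start + len(self.up2)

    @property
    def r2_flank_start(self) -> int:
        """Start of the MS-proximal (right, reverse-complemented) flank in read 2."""
        return self.r2_vt2_start + self.vt2_len

    @property
    def r2_ms_start(self) -> int:
        return self.r2_flank_start + len(self.right_flank)

    # ---- serialization ----

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ms"] = {"unit": self.ms.unit, "expected_units": self.ms.expected_units}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ReadArchitecture":
        d = dict(d)
        ms = d.pop("ms")
        return cls(ms=MicrosatelliteDef(**ms), **d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ReadArchitecture":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# Default synthetic-template designs.  The primers and flanks are cytosine-free
# so they survive bisulfite treatment intact; the flanks carry no tandem repeat
# of the tract unit at their MS-proximal ends.
_UP1 = "AGGTAGTGAGTTGATGGAGT"
_UP2 = "TGAGGTTAGAGGTAGTGTGA"
_UP3 = "GGAGTTGAGTAGTGGTTAGG"
_LEFT_FLANK = "TAGGATTGGAGATGGTTGAG"
_RIGHT_FLANK = "TGAGTTGGTAGAGTTAGGTG"

MONO_C_18 = MicrosatelliteDef("C", 18)
DI_CA_13 = MicrosatelliteDef("CA", 13)
MONO_A_17 = MicrosatelliteDef("A", 17)


def default_architecture(ms: MicrosatelliteDef = MONO_C_18, **kw) -> ReadArchitecture:
    """A ready-to-use synthetic-template architecture for the given tract."""
    return ReadArchitecture(
        up1=_UP1, up2=_UP2, up3=_UP3,
        left_flank=_LEFT_FLANK, right_flank=_RIGHT_FLANK,
        ms=ms, **kw,
    )
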