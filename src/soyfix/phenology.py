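"""Soybean growth staging and the continuous relative-phenology time axis.

The Fehr staging system (VE emergence, V*n* vegetative nodes, R1–R8
reproductive stages) is ordinal, not continuous, so it cannot serve directly
as the time axis of a nonlinear growth model.  This module maps Fehr stage
codes onto a dimensionless relative-phenology scale in which 0 is emergence
(VE), 1 is beginning pod (R3) and 2 is beginning physiological maturity
(R7); late stages run on to R8 = 2.5.  The mapping is anchored by a table of
(stage, value) pairs produced by a phenology simulator for the underlying
field studies; stages between anchors are linearly interpolated in stage
number.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "StageCode",
    "StageAnchorTable",
    "PhenologyError",
    "parse_stage",
    "stage_to_relative",
    "default_anchor_table",
    "load_anchor_table",
]

#: Highest admissible reproductive stage number (R8 = full maturity).
R_MAX = 8.0

_STAGE_RE = re.compile(r"^(?:VE|V(\d+)|R(\d(?:\.\d)?))$")


class PhenologyError(ValueError):
    """Malformed stage code or stage outside the anchored range."""


@dataclass(frozen=True, order=True)
class StageCode:
    """A Fehr growth stage.

    ``phase`` is 0 for VE, 1 for vegetative (V) and 2 for reproductive (R)
    stages; the ordering induced by (phase, number) is developmental order.
    VE carries number 0 by convention.
    """

    phase: int
    number: float

    def __str__(self) -> str:
        if self.phase == 0:
            return "VE"
        letter = "V" if self.phase == 1 else "R"
        n = self.number
        return f"{letter}{int(n)}" if n == int(n) else f"{letter}{n}"


def parse_stage(code: str) -> StageCode:
    """Parse a stage label such as ``"VE"``, ``"V4"`` or ``"R5.5"``.

    Parsing is case-insensitive and tolerates surrounding whitespace.
    V stages must be integers >= 1; R stages must lie in [1, 8] (one decimal
    digit permitted, e.g. R5.5 or R6.2).
    """
    if not isinstance(code, str):
        raise PhenologyError(f"stage code must be text, got {code!r}")
    token = code.strip().upper()
    m = _STAGE_RE.match(token)
    if m is None:
        raise PhenologyError(f"unrecognized growth-stage code {code!r}")
    if token == "VE":
        return StageCode(0, 0.0)
    if m.group(1) is not None:
        n = int(m.group(1))
        if n < 1:
            raise PhenologyError(f"vegetative stage number must be >= 1 in {code!r}")
        return StageCode(1, float(n))
    n = float(m.group(2))
    if not 1.0 <= n <= R_MAX:
        raise PhenologyError(f"reproductive stage number {n} outside [1, 8] in {code!r}")
    return StageCode(2, n)


class StageAnchorTable:
    """Ordered (StageCode, relative value) anchors defining the time axis.

    Anchor values must be nondecreasing in developmental order.  Lookup
    returns the tabulated value for listed stages and interpolates linearly
    (in stage number) between the bracketing anchors otherwise.
    """

    def __init__(self, pairs: list[tuple[StageCode, float]]):
        if not pairs:
            raise PhenologyError("anchor table must contain at least one stage")
        pairs = sorted(pairs, key=lambda p: p[0])
        values = [v for _, v in pairs]
        if any(b < a for a, b in zip(values, values[1:])):
            raise PhenologyError("anchor values must be nondecreasing in developmental order")
        self.pairs = pairs
        self._exact = {s: v for s, v in pairs}

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StageAnchorTable":
        return cls([(parse_stage(s), float(v)) for s, v in zip(df["stage"], df["relative_value"])])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": [str(s) for s, _ in self.pairs], "relative_value": [v for _, v in self.pairs]}
        )

    # -- lookup ----------------------------------------------------------

    def relative(self, stage: StageCode) -> float:
        if stage in self._exact:
            return self._exact[stage]
        lower = [(s, v) for s, v in self.pairs if s < stage]
        upper = [(s, v) for s, v in self.pairs if s > stage]
        if not lower:
            raise PhenologyError(f"stage {stage} precedes the first anchor {self.pairs[0][0]}")
        if not upper:
            raise PhenologyError(f"stage {stage} is beyond the last anchor {self.pairs[-1][0]}")
        (s0, v0), (s1, v1) = lower[-1], upper[0]
        return _interpolate(stage, s0, v0, s1, v1)


def _interpolate(stage: StageCode, s0: StageCode, v0: float, s1: StageCode, v1: float) -> float:
    if v1 == v0:
        return v0
    if s0.phase == s1.phase:
        frac = (stage.number - s0.number) / (s1.number - s0.number)
    elif stage.phase == s0.phase == 1 and s1.phase == 2:
        # V stage above the last tabulated V anchor: approach R1's value,
        # nominally reached five nodes past the last anchor.
        frac = min(1.0, (stage.number - s0.number) / 5.0)
    elif s0.phase == 0 and stage.phase == 1:
        # between emergence (treated as node 0) and the first V anchor
        frac = stage.number / s1.number
    else:  # pragma: no cover - anchor tables with VE and R only
        frac = 0.5
    return v0 + frac * (v1 - v0)


def stage_to_relative(stage: StageCode | str, anchors: StageAnchorTable | None = None) -> float:
    """Map a stage (code or label) to relative phenology t in [0, 2.5]."""
    if isinstance(stage, str):
        stage = parse_stage(stage)
    if anchors is None:
        anchors = default_anchor_table()
    return anchors.relative(stage)


def load_anchor_table(path) -> StageAnchorTable:
    """Read a two-column CSV (stage, relative_value) as an anchor table."""
    return StageAnchorTable.from_frame(pd.read_csv(path))


_DEFAULT: StageAnchorTable | None = None


def default_anchor_table() -> StageAnchorTable:
    """The packaged anchor table (union of the source studies' schedules).

    Where schedules disagree on a stage (V4 printed as both 0.40 and 0.44,
    V6 as 0.60 and 0.62) the densest schedule's value is used.
    """
    global _DEFAULT
    if _DEFAULT is None:
        with resources.files("soyfix.data").joinpath("stage_anchors.csv").open("r") as fh:
            _DEFAULT = StageAnchorTable.from_frame(pd.read_csv(fh))
    return _DEFAULT
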