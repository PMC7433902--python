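"""Mother/daughter age assignment and marker-asymmetry classification.

Centriolar age is read from total Asl (Asterless): the centriole with the
larger background-corrected Asl total is the mother, because Asl loads
progressively onto the growing daughter.  Marker asymmetry is then the
daughter/mother total-intensity ratio, binned into the field's timeline
categories:

* ``transition``  — ratio < 2 (marker still on both centrioles)
* ``strong``      — 2 <= ratio <= 10 (predominantly on the daughter)
* ``complete``    — ratio > 10, including +inf (daughter only)
* ``single_positive`` / ``single_negative`` — centrosomes with a single
  detectable centriole, with/without marker signal
* ratio < 1 additionally flags *inverted* asymmetry (marker biased to the
  mother), the readout used for perturbation phenotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import CentrioleMeasurement

CATEGORIES = ["single_positive", "single_negative", "transition", "strong", "complete"]

#: category boundaries on the daughter/mother ratio scale
TRANSITION_STRONG_BOUNDARY = 2.0
STRONG_COMPLETE_BOUNDARY = 10.0

DEFAULT_TIE_TOLERANCE = 0.05


@dataclass
class CentriolePair:
    """Two measured centrioles of one centrosome with age assignment."""

    cell_id: str
    a: CentrioleMeasurement
    b: CentrioleMeasurement
    asl_channel: str
    assignment: str  # "A_mother" | "B_mother" | "ambiguous"
    asl_ratio: float | None = None  # mother/daughter Asl, >= 1 when unambiguous

    @property
    def mother(self) -> CentrioleMeasurement:
        if self.assignment == "A_mother":
            return self.a
        if self.assignment == "B_mother":
            return self.b
        raise ValueError("ambiguous assignment has no mother")

    @property
    def daughter(self) -> CentrioleMeasurement:
        return self.b if self.assignment == "A_mother" else self.a

    def cnb_reference_ratio(self, marker_channel: str) -> float | None:
        """Asl(marker+)/Asl(marker-) — the age-validation convention.

        The marker-bearing centriole (presumed daughter) Asl total divided by
        the marker-free (presumed mother) Asl total; None when the marker does
        not single out one centriole.
        """
        ta, tb = self.a.total(marker_channel), self.b.total(marker_channel)
        if (ta > 0) == (tb > 0):
            return None
        pos, neg = (self.a, self.b) if ta > tb else (self.b, self.a)
        asl_neg = neg.total(self.asl_channel)
        if asl_neg <= 0:
            return math.inf
        return pos.total(self.asl_channel) / asl_neg


@dataclass
class AsymmetryRecord:
    """One centrosome's marker ratio, category and annotations."""

    cell_id: str
    stage: str
    centrosome_position: str
    marker_channel: str
    ratio: float | None  # daughter/mother in [0, inf]; None for single centrioles
    category: str
    inverted: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES + ["no_marker"]:
            raise ValueError(f"unknown category {self.category!r}")


def assign_age(
    a: CentrioleMeasurement,
    b: CentrioleMeasurement,
    asl_channel: str,
    tie_tolerance: float = DEFAULT_TIE_TOLERANCE,
    cell_id: str | None = None,
) -> CentriolePair:
    """Assign mother/daughter identity from total Asl.

    The brighter-Asl centriole is the mother.  When the relative difference
    is within ``tie_tolerance`` of the larger total the pair is marked
    ``ambiguous`` and excluded from ratio statistics downstream.
    """
    if not a.ok or not b.ok:
        raise ValueError("both measurements must be unflagged for age assignment")
    ta, tb = a.total(asl_channel), b.total(asl_channel)
    if ta <= 0 and tb <= 0:
        raise ValueError("no Asl signal on either centriole")
    cell_id = cell_id if cell_id is not None else (a.cell_id or b.cell_id)
    hi, lo = max(ta, tb), min(ta, tb)
    if hi - lo <= tie_tolerance * hi:
        return CentriolePair(cell_id, a, b, asl_channel, "ambiguous")
    assignment = "A_mother" if ta > tb else "B_mother"
    return CentriolePair(cell_id, a, b, asl_channel, assignment, asl_ratio=hi / lo)


def asymmetry_ratio(
    pair: CentriolePair, marker_channel: str, detection_floor: float = 0.0
) -> float | None:
    """Daughter/mother total-intensity ratio for a marker channel.

    Mother at/below the detection floor with a detectable daughter gives
    +inf (marker exclusively on the daughter).  Both below the floor gives
    None — a marker-free centrosome, excluded from ratio plots.
    """
    if pair.assignment == "ambiguous":
        raise ValueError("cannot compute a ratio for an ambiguous pair")
    d = pair.daughter.total(marker_channel)
    m = pair.mother.total(marker_channel)
    if m <= detection_floor:
        if d <= detection_floor:
            return None
        return math.inf
    return d / m


def classify(
    ratio: float | None = None, *, single: bool = False, marker_present: bool = True
) -> str:
    """Bin a centrosome into the asymmetry-timeline categories.

    Two-centriole centrosomes are classified on the daughter/mother ratio;
    single-centriole centrosomes (e.g. pre-duplication interphase) on marker
    presence alone.
    """
    if single:
        return "single_positive" if marker_present else "single_negative"
    if ratio is None:
        return "no_marker"
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    if ratio < TRANSITION_STRONG_BOUNDARY:
        return "transition"
    if ratio <= STRONG_COMPLETE_BOUNDARY:
        return "strong"
    return "complete"


def make_record(
    pair: CentriolePair,
    marker_channel: str,
    stage: str,
    centrosome_position: str = "unknown",
    detection_floor: float = 0.0,
) -> AsymmetryRecord:
    """Ratio + category + inversion flag for one measured centrosome."""
    ratio = asymmetry_ratio(pair, marker_channel, detection_floor)
    category = classify(ratio)
    return AsymmetryRecord(
        cell_id=pair.cell_id,
        stage=stage,
        centrosome_position=centrosome_position,
        marker_channel=marker_channel,
        ratio=ratio,
        category=category,
        inverted=(ratio is not None and math.isfinite(ratio) and ratio < 1.0),
    )


def timeline_fractions(
    records: list[AsymmetryRecord], by_position: bool = True
) -> pd.DataFrame:
    """Per (stage, position) fraction of each category, with group sizes.

    This is the timeline bar chart in tabular form: each row is one bar
    group; category fractions sum to 1 within the row.
    """
    if not records:
        raise ValueError("no records")
    rows = [
        dict(stage=r.stage, position=r.centrosome_position, category=r.category)
        for r in records
    ]
    df = pd.DataFrame(rows)
    keys = ["stage", "position"] if by_position else ["stage"]
    out = []
    for key, grp in df.groupby(keys, sort=False):
        if not isinstance(key, tuple):
            key = (key,)
        counts = grp["category"].value_counts()
        n = len(grp)
        row = dict(zip(keys, key)) | {"n": n}
        for cat in CATEGORIES + ["no_marker"]:
            row[cat] = counts.get(cat, 0) / n
        out.append(row)
    return pd.DataFrame(out)


def inverted_fraction(
    records: list[AsymmetryRecord],
    stages: set[str] = frozenset({"metaphase", "anaphase"}),
) -> tuple[float, int, int]:
    """Fraction of two-centriole centrosomes with daughter/mother ratio < 1.

    Restricted by default to metaphase and anaphase, the stages where the
    asymmetry should be fully established.  Returns (fraction, n_inverted, n).
    """
    eligible = [r for r in records if r.stage in stages and r.ratio is not None]
    if not eligible:
        return float("nan"), 0, 0
    n_inv = sum(r.inverted for r in eligible)
    return n_inv / len(eligible), n_inv, len(eligible)


def qc_summary(pairs: list[CentriolePair]) -> dict:
    """Counts of ambiguous/flagged pairs excluded from ratio statistics."""
    n_ambiguous = sum(p.assignment == "ambiguous" for p in pairs)
    flagged = sum((not p.a.ok) or (not p.b.ok) for p in pairs)
    return {
        "n_pairs": len(pairs),
        "n_ambiguous": n_ambiguous,
        "n_flagged_measurements": flagged,
        "n_usable": len(pairs) - n_ambiguous,
    }
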