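"""Raw-count positivity calling, marker set-overlap analysis and growth-plate
zone proportions.

Positivity is the raw-count rule: a cell is positive for a marker iff its UMI
count for that gene is strictly greater than 0 — no normalization, no
threshold. The overlap analysis builds the full sign-pattern contingency
table over a marker panel and derives per-marker percentages, conditional
positivity, and exclusivity summaries, optionally restricted to the cells
positive for a reference marker (as done when asking how stem-cell subset
markers partition the Apoe-positive resting chondrocytes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, ValidationError

__all__ = [
    "PositivityTable",
    "OverlapReport",
    "call_positivity",
    "overlap_analysis",
    "zone_proportions",
    "round_half_away",
    "ZONES",
]

ZONES = ("RZ", "PZ", "HZ")


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (printed-precision
    comparisons; Python's round() would round halves to even)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass
class PositivityTable:
    """Boolean cells x markers matrix derived from raw counts."""

    flags: np.ndarray
    cell_ids: tuple[str, ...]
    marker_ids: tuple[str, ...]

    def __post_init__(self):
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.shape != (len(self.cell_ids), len(self.marker_ids)):
            raise ValidationError("positivity table shape does not match ids")

    @property
    def n_cells(self) -> int:
        return self.flags.shape[0]

    def column(self, marker: str) -> np.ndarray:
        try:
            j = self.marker_ids.index(marker)
        except ValueError:
            raise ValidationError(f"unknown marker {marker!r}") from None
        return self.flags[:, j]


def call_positivity(m: ExpressionMatrix, markers: list[str]) -> PositivityTable:
    """Flag each cell positive for each marker iff raw count > 0."""
    missing = [g for g in markers if g not in m.gene_ids]
    if missing:
        raise ValidationError(f"markers not in matrix: {missing}")
    cols = [m.gene_ids.index(g) for g in markers]
    flags = m.counts[:, cols].toarray() > 0
    return PositivityTable(flags.reshape(m.n_cells, len(markers)),
                           m.cell_ids, tuple(markers))


def _pattern_key(bools) -> str:
    return "".join("+" if b else "-" for b in bools)


@dataclass
class OverlapReport:
    """Full sign-pattern table over a marker panel plus derived summaries.

    ``pattern_counts`` keys are +/- strings in marker order over all cells.
    ``k_positive_counts`` counts cells by how many of the *non-reference*
    markers they are positive for, restricted to reference-positive cells
    when a reference is set (otherwise k over all markers, all cells).
    ``conditional_pct[(A, B)]`` is the percentage of B-positive cells that
    are also A-positive; None when there are no B-positive cells.
    """

    n_cells: int
    marker_ids: tuple[str, ...]
    per_marker_count: dict[str, int]
    per_marker_pct: dict[str, float]
    pattern_counts: dict[str, int]
    k_positive_counts: dict[int, int]
    conditional_pct: dict[tuple[str, str], float | None]
    reference: str | None = None
    reference_positive_count: int | None = None

    def __post_init__(self):
        if sum(self.pattern_counts.values()) != self.n_cells:
            raise ValidationError("pattern counts do not sum to n_cells")
        for j, mk in enumerate(self.marker_ids):
            implied = sum(
                n for pat, n in self.pattern_counts.items() if pat[j] == "+"
            )
            if implied != self.per_marker_count[mk]:
                raise ValidationError(
                    f"per-marker count for {mk} inconsistent with patterns"
                )
        # inclusion-exclusion coherence: sum_k k * N_k equals the sum of
        # per-marker counts within the sub-population the k-counts cover.
        if self.reference is None:
            lhs = sum(k * n for k, n in self.k_positive_counts.items())
            rhs = sum(self.per_marker_count.values())
            if lhs != rhs:
                raise ValidationError("k-positive counts violate inclusion-exclusion")

    # -- derived quantities -------------------------------------------------

    def pct_reference_all_negative(self) -> float:
        """Among reference-positive cells, % negative for every other marker."""
        if self.reference is None or not self.reference_positive_count:
            raise ValidationError("requires a reference marker with positive cells")
        return 100.0 * self.k_positive_counts.get(0, 0) / self.reference_positive_count

    def pct_single_among_any(self) -> float | None:
        """Among reference-positive cells positive for >= 1 other marker,
        % positive for exactly one (marker exclusivity)."""
        if self.reference is None:
            raise ValidationError("requires a reference marker")
        at_least_one = sum(n for k, n in self.k_positive_counts.items() if k >= 1)
        if at_least_one == 0:
            return None
        return 100.0 * self.k_positive_counts.get(1, 0) / at_least_one

    def triple_positive_count(self) -> int:
        """Reference-positive cells positive for all other markers (or, with
        no reference, cells positive for every marker)."""
        n_other = len(self.marker_ids) - (1 if self.reference else 0)
        return sum(n for k, n in self.k_positive_counts.items() if k == n_other)

    def to_dict(self) -> dict:
        """JSON-friendly form; undefined conditionals serialize as 'NA'."""
        cond = {
            f"{a}|{b}": ("NA" if v is None else v)
            for (a, b), v in self.conditional_pct.items()
        }
        out = {
            "n_cells": self.n_cells,
            "markers": list(self.marker_ids),
            "per_marker_count": dict(self.per_marker_count),
            "per_marker_pct": dict(self.per_marker_pct),
            "pattern_counts": dict(self.pattern_counts),
            "k_positive_counts": {str(k): v for k, v in
                                  sorted(self.k_positive_counts.items())},
            "conditional_pct": cond,
            "reference": self.reference,
        }
        if self.reference is not None:
            out["reference_positive_count"] = self.reference_positive_count
            if self.reference_positive_count:
                out["pct_reference_all_negative"] = self.pct_reference_all_negative()
            single = self.pct_single_among_any()
            out["pct_single_among_any"] = "NA" if single is None else single
        return out


def overlap_analysis(
    p: PositivityTable, reference: str | None = None
) -> OverlapReport:
    if len(p.marker_ids) < 1:
        raise ValidationError("need at least one marker")
    flags = p.flags
    n = p.n_cells

    per_count = {
        mk: int(flags[:, j].sum()) for j, mk in enumerate(p.marker_ids)
    }
    per_pct = {mk: 100.0 * c / n if n else 0.0 for mk, c in per_count.items()}

    pattern_counts: dict[str, int] = {}
    for row in flags:
        key = _pattern_key(row)
        pattern_counts[key] = pattern_counts.get(key, 0) + 1

    conditional: dict[tuple[str, str], float | None] = {}
    for jb, b in enumerate(p.marker_ids):
        denom = per_count[b]
        for ja, a in enumerate(p.marker_ids):
            if a == b:
                continue
            if denom == 0:
                conditional[(a, b)] = None
            else:
                both = int((flags[:, ja] & flags[:, jb]).sum())
                conditional[(a, b)] = 100.0 * both / denom

    ref_count = None
    if reference is not None:
        ref_col = p.column(reference)
        ref_count = int(ref_col.sum())
        other_j = [j for j, mk in enumerate(p.marker_ids) if mk != reference]
        k_of = flags[np.ix_(ref_col, other_j)].sum(axis=1) if ref_count else \
            np.array([], dtype=int)
        k_counts = {int(k): int(c) for k, c in
                    zip(*np.unique(k_of, return_counts=True))}
    else:
        k_of = flags.sum(axis=1)
        k_counts = {int(k): int(c) for k, c in
                    zip(*np.unique(k_of, return_counts=True))}

    return OverlapReport(
        n_cells=n,
        marker_ids=p.marker_ids,
        per_marker_count=per_count,
        per_marker_pct=per_pct,
        pattern_counts=pattern_counts,
        k_positive_counts=k_counts,
        conditional_pct=conditional,
        reference=reference,
        reference_positive_count=ref_count,
    )


def zone_proportions(table: pd.DataFrame) -> dict[str, float]:
    """Growth-plate zone extents from per-cell axial positions and zone labels.

    The table needs columns ``axial_position`` (finite reals, increasing from
    the resting zone toward the hypertrophic zone) and ``zone_label`` in
    {RZ, PZ, HZ}, each zone with >= 1 cell. Two changepoints are fitted by an
    exhaustive scan over midpoints between adjacent distinct positions,
    minimizing total label misclassification (cells below the first boundary
    called RZ, between called PZ, above called HZ); ties resolve toward the
    smaller RZ. Each zone's extent is reported as a percentage of the span
    between the first and last cell; percentages sum to 100.
    """
    if not {"axial_position", "zone_label"}.issubset(table.columns):
        raise ValidationError("table needs axial_position and zone_label columns")
    pos = table["axial_position"].to_numpy(dtype=float)
    lab = table["zone_label"].to_numpy()
    if not np.all(np.isfinite(pos)):
        raise ValidationError("non-finite axial position")
    bad = set(lab) - set(ZONES)
    if bad:
        raise ValidationError(f"unknown zone labels: {sorted(bad)}")
    for z in ZONES:
        if not np.any(lab == z):
            raise ValidationError(f"zone {z} has no cells")

    order = np.argsort(pos, kind="stable")
    pos_s, lab_s = pos[order], lab[order]
    distinct = np.unique(pos_s)
    if distinct.size < 3:
        raise ValidationError("need at least 3 distinct axial positions")
    cuts = (distinct[:-1] + distinct[1:]) / 2.0

    # prefix counts of each zone label along the sorted axis, evaluated at
    # each candidate cut (number of cells strictly below the cut)
    n_below = np.searchsorted(pos_s, cuts, side="right")
    prefix = {z: np.concatenate([[0], np.cumsum(lab_s == z)]) for z in ZONES}
    n = pos_s.size
    tot = {z: int(prefix[z][-1]) for z in ZONES}

    best = None  # (misclassification, i, j)
    for i, bi in enumerate(n_below):
        rz_ok = prefix["RZ"][bi]
        for j in range(i + 1, len(cuts)):
            bj = n_below[j]
            pz_ok = prefix["PZ"][bj] - prefix["PZ"][bi]
            hz_ok = tot["HZ"] - prefix["HZ"][bj]
            mis = n - (rz_ok + pz_ok + hz_ok)
            if best is None or mis < best[0]:
                best = (mis, i, j)
    if best is None:
        raise ValidationError("no valid boundary pair (too few distinct positions)")
    _, i, j = best
    b1, b2 = float(cuts[i]), float(cuts[j])
    lo, hi = float(pos_s[0]), float(pos_s[-1])
    span = hi - lo
    return {
        "RZ": 100.0 * (b1 - lo) / span,
        "PZ": 100.0 * (b2 - b1) / span,
        "HZ": 100.0 * (hi - b2) / span,
    }
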