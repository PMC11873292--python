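"""Synthetic inputs with known ground truth.

Three generators:

* :func:`generate_counts` — clustered negative-binomial UMI count matrices
  with planted pan-markers (high in-cluster positivity, large fold change
  against every other cluster) and planted subset markers (low positivity,
  cluster-restricted), emulating the five growth-plate chondrocyte clusters
  (resting, mitotic, proliferative, pre-hypertrophic/hypertrophic-like).
* :func:`build_rc_fixture` — an exact single-cluster fixture of the resting
  chondrocyte marker-overlap structure: 1 359 cells over the four markers
  Apoe/Pthlh/Axin2/Foxa2 whose joint positivity pattern realizes the
  published per-marker and overlap totals. The published report fixes only
  marginals and overlap sums; the split of the 15 Apoe+ double-positive
  cells across marker pairs is not published, so the default table assigns
  them all to the Pthlh-Foxa2 pair and keeps the Apoe- marker positives
  mutually exclusive — any consistent assignment yields identical values
  for every quantity the downstream analysis reports.
* :func:`generate_flow_events` — bimodal surface-marker intensity events
  filling a gating tree's denominator compartment with requested population
  fractions; remainder events satisfy the denominator chain but fail every
  population signature.

All randomness flows from one integer seed through a counter-based Philox
generator, so outputs are bit-reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.optimize import brentq

from .core import ClusterLabeling, ExpressionMatrix, ValidationError
from .gating import GatingTree, default_gating_tree

__all__ = [
    "PlantedMarker",
    "SyntheticSpec",
    "RcFixtureSpec",
    "DEFAULT_RC_JOINT_COUNTS",
    "RC_MARKERS",
    "generate_counts",
    "build_rc_fixture",
    "generate_flow_events",
]


# ---------------------------------------------------------------------------
# Clustered NB counts with planted markers


@dataclass(frozen=True)
class PlantedMarker:
    """A gene planted with known positivity and fold-change structure.

    ``fold_change`` is the ratio of the target-cluster mean to every other
    cluster's mean (= ``background_mean``). In the target cluster the gene is
    a zero-inflated, zero-truncated NB: a cell expresses with probability
    ``in_cluster_positivity`` and, if it does, draws a count >= 1, so the
    expected positivity is exact and decoupled from the fold change.
    """

    gene_id: str
    target_cluster: str
    in_cluster_positivity: float
    fold_change: float
    background_mean: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.in_cluster_positivity <= 1.0:
            raise ValidationError("in_cluster_positivity must be in [0, 1]")
        if self.fold_change < 1.0:
            raise ValidationError("fold_change must be >= 1")
        if self.background_mean < 0.0:
            raise ValidationError("background_mean must be >= 0")


@dataclass
class SyntheticSpec:
    clusters: list[tuple[str, int]]
    n_genes: int
    baseline_mean: float = 0.5
    dispersion: float = 1.0
    planted_markers: list[PlantedMarker] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if not self.clusters:
            raise ValidationError("spec needs at least one cluster")
        names = [c for c, _ in self.clusters]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate cluster names")
        for name, n in self.clusters:
            if n < 1:
                raise ValidationError(f"cluster {name!r} needs >= 1 cell")
        if self.n_genes < len(self.planted_markers):
            raise ValidationError("n_genes smaller than number of planted markers")
        if not (np.isfinite(self.baseline_mean) and self.baseline_mean > 0):
            raise ValidationError("baseline_mean must be finite and > 0")
        if not (np.isfinite(self.dispersion) and self.dispersion > 0):
            raise ValidationError("dispersion must be finite and > 0")
        for pm in self.planted_markers:
            if pm.target_cluster not in names:
                raise ValidationError(
                    f"planted marker {pm.gene_id!r} targets unknown cluster "
                    f"{pm.target_cluster!r}"
                )


def _nb_p(mean: float, size: float) -> float:
    return size / (size + mean)


def _ztnb_mu(trunc_mean: float, size: float) -> float:
    """NB mean whose zero-truncated mean equals ``trunc_mean`` (>= 1)."""
    if trunc_mean < 1.0 + 1e-12:
        raise ValidationError(
            f"expressed-cell mean {trunc_mean:.3g} infeasible: a positive count "
            "is at least 1"
        )

    def h(mu):
        p0 = _nb_p(mu, size) ** size
        return mu / (1.0 - p0) - trunc_mean

    lo, hi = 1e-9, max(trunc_mean, 1.0)
    while h(hi) < 0:
        hi *= 2
    return float(brentq(h, lo, hi, xtol=1e-12))


def _sample_ztnb(rng, mu: float, size: float, n: int) -> np.ndarray:
    """Zero-truncated NB via inverse CDF on the uniform slice above P(X=0)."""
    p = _nb_p(mu, size)
    p0 = p ** size
    u = rng.uniform(p0, 1.0, size=n)
    return stats.nbinom.ppf(u, size, p).astype(np.int64)


def generate_counts(spec: SyntheticSpec) -> tuple[ExpressionMatrix, ClusterLabeling]:
    """Draw a clustered UMI count matrix per the spec; deterministic per seed.

    Background genes share one NB(baseline_mean, dispersion) across clusters.
    Planted markers draw NB(background_mean, dispersion) in non-target
    clusters and the zero-inflated truncated NB described on
    :class:`PlantedMarker` in the target cluster, with expressed-cell mean
    solved so the target-cluster mean equals fold_change * background_mean
    (unit reference mean when background_mean is 0).
    """
    rng = np.random.Generator(np.random.Philox(key=spec.seed))
    cluster_names = [c for c, _ in spec.clusters]
    sizes = {c: n for c, n in spec.clusters}
    n_cells = sum(sizes.values())
    r = spec.dispersion

    cell_ids, cell_clusters = [], []
    for name in cluster_names:
        for i in range(sizes[name]):
            cell_ids.append(f"{name}_cell{i:05d}")
            cell_clusters.append(name)
    cluster_rows = {}
    start = 0
    for name in cluster_names:
        cluster_rows[name] = np.arange(start, start + sizes[name])
        start += sizes[name]

    planted = {pm.gene_id: pm for pm in spec.planted_markers}
    if len(planted) != len(spec.planted_markers):
        raise ValidationError("duplicate planted marker gene ids")
    gene_ids = list(planted) + [
        f"gene{i:05d}" for i in range(spec.n_genes - len(planted))
    ]

    counts = np.zeros((n_cells, spec.n_genes), dtype=np.int64)

    for j, g in enumerate(gene_ids):
        pm = planted.get(g)
        if pm is None:
            counts[:, j] = rng.negative_binomial(
                r, _nb_p(spec.baseline_mean, r), size=n_cells
            )
            continue
        pi = pm.in_cluster_positivity
        ref = pm.background_mean if pm.background_mean > 0 else 1.0
        target_mean = pm.fold_change * ref
        if pi == 0.0:
            if target_mean > 0 and pm.background_mean > 0:
                raise ValidationError(
                    f"planted marker {g!r}: positive target mean with zero "
                    "positivity is infeasible"
                )
        for name in cluster_names:
            rows = cluster_rows[name]
            if name == pm.target_cluster:
                if pi > 0.0:
                    mu = _ztnb_mu(target_mean / pi, r)
                    on = rng.random(rows.size) < pi
                    vals = np.zeros(rows.size, dtype=np.int64)
                    vals[on] = _sample_ztnb(rng, mu, r, int(on.sum()))
                    counts[rows, j] = vals
            else:
                if pm.background_mean > 0:
                    counts[rows, j] = rng.negative_binomial(
                        r, _nb_p(pm.background_mean, r), size=rows.size
                    )

    m = ExpressionMatrix(sp.csr_array(counts), gene_ids, cell_ids)
    labels = ClusterLabeling.from_sequences(cell_ids, cell_clusters)
    return m, labels


# ---------------------------------------------------------------------------
# Exact resting-chondrocyte overlap fixture

RC_MARKERS = ("Apoe", "Pthlh", "Axin2", "Foxa2")

# Sign patterns over (Apoe, Pthlh, Axin2, Foxa2). Marginals and overlap sums
# match the published totals; see module docstring for the one unconstrained
# choice (the 15 Apoe+ double-positives sit in the Pthlh-Foxa2 pair).
DEFAULT_RC_JOINT_COUNTS: dict[str, int] = {
    "+---": 1023,  # Apoe only
    "++--": 218,
    "+-+-": 32,
    "+--+": 36,
    "++-+": 15,    # the Apoe+ double-positives
    "-+--": 4,
    "---+": 6,
    "----": 25,
}


@dataclass
class RcFixtureSpec:
    total_cells: int = 1359
    joint_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_RC_JOINT_COUNTS)
    )

    def __post_init__(self):
        for pat, n in self.joint_counts.items():
            if len(pat) != len(RC_MARKERS) or set(pat) - {"+", "-"}:
                raise ValidationError(f"malformed sign pattern {pat!r}")
            if n < 0:
                raise ValidationError(f"negative count for pattern {pat!r}")
        total = sum(self.joint_counts.values())
        if total != self.total_cells:
            raise ValidationError(
                f"joint counts sum to {total}, expected total_cells="
                f"{self.total_cells}"
            )

    def marginal(self, marker: str) -> int:
        j = RC_MARKERS.index(marker)
        return sum(n for pat, n in self.joint_counts.items() if pat[j] == "+")


def build_rc_fixture(
    spec: RcFixtureSpec | None = None,
) -> tuple[ExpressionMatrix, ClusterLabeling]:
    """Materialize the single-cluster ('RC') overlap fixture.

    Positive entries get count 1 (the positivity rule is count > 0, so
    magnitude is irrelevant downstream); cells appear grouped by pattern.
    """
    spec = spec or RcFixtureSpec()
    rows = []
    cell_ids = []
    i = 0
    for pat in sorted(spec.joint_counts):
        vec = [1 if s == "+" else 0 for s in pat]
        for _ in range(spec.joint_counts[pat]):
            rows.append(vec)
            cell_ids.append(f"RC_cell{i:04d}")
            i += 1
    counts = np.array(rows, dtype=np.int64).reshape(len(cell_ids), len(RC_MARKERS))
    m = ExpressionMatrix(sp.csr_array(counts), list(RC_MARKERS), cell_ids)
    labels = ClusterLabeling.from_sequences(cell_ids, ["RC"] * len(cell_ids))
    return m, labels


# ---------------------------------------------------------------------------
# Flow-cytometry events


@dataclass(frozen=True)
class ChannelModel:
    """Bimodal log-intensity model: modes at threshold +/- separation,
    spread sd; guaranteed-side draws use threshold +/- |N(separation, sd)|."""

    separation: float = 2.0
    sd: float = 0.5


def generate_flow_events(
    n_events: int,
    populations: list[tuple[str, float]],
    channel_model: ChannelModel | dict[str, ChannelModel] | None = None,
    seed: int = 0,
    tree: GatingTree | None = None,
    denominator: str = "mCherry+",
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw surface-marker intensity events for a gating tree.

    Every event satisfies the denominator chain; events of a requested
    population additionally satisfy exactly that population's own predicate
    chain, and remainder ('other') events are built to fail every
    population's signature. Returns (event table, ground-truth labels).
    """
    tree = tree or default_gating_tree()
    if channel_model is None:
        channel_model = ChannelModel()
    frac_names = [name for name, _ in populations]
    for name in frac_names:
        if name not in tree.populations:
            raise ValidationError(f"unknown population {name!r}")
    fracs = np.array([f for _, f in populations], dtype=float)
    if np.any(fracs < 0) or fracs.sum() > 1.0 + 1e-9:
        raise ValidationError("population fractions must be >= 0 and sum to <= 1")

    rng = np.random.Generator(np.random.Philox(key=seed))
    channels = tree.channels()

    def model_for(ch: str) -> ChannelModel:
        if isinstance(channel_model, dict):
            return channel_model.get(ch, ChannelModel())
        return channel_model

    # required channel signs per truth label
    def chain_signs(name: str) -> dict[str, tuple[str, float]]:
        return {c.channel: (c.sign, c.threshold) for c in tree.chain(name)}

    other_signs = chain_signs(denominator)
    for pop in tree.populations:
        # pin one violated condition per population not already excluded
        excluded = False
        for c in tree.chain(pop):
            got = other_signs.get(c.channel)
            if got is not None and got[0] != c.sign:
                excluded = True
                break
        if excluded:
            continue
        for c in tree.chain(pop):
            if c.channel not in other_signs:
                flip = "-" if c.sign == "+" else "+"
                other_signs[c.channel] = (flip, c.threshold)
                excluded = True
                break
        if not excluded:
            raise ValidationError(
                f"cannot construct 'other' events excluded from {pop!r}"
            )

    sign_maps = {name: chain_signs(name) for name in tree.populations}
    sign_maps["other"] = other_signs

    p = np.concatenate([fracs, [max(0.0, 1.0 - fracs.sum())]])
    p = p / p.sum()
    choices = frac_names + ["other"]
    truth = rng.choice(len(choices), size=n_events, p=p)
    truth_names = np.array(choices, dtype=object)[truth]

    data = np.empty((n_events, len(channels)))
    for j, ch in enumerate(channels):
        cm = model_for(ch)
        mag = np.abs(rng.normal(cm.separation, cm.sd, size=n_events))
        side = np.where(rng.random(n_events) < 0.5, 1.0, -1.0)  # unpinned default
        thr = np.zeros(n_events)
        for name in choices:
            mask = truth_names == name
            pin = sign_maps[name].get(ch)
            if pin is not None:
                side[mask] = 1.0 if pin[0] == "+" else -1.0
                thr[mask] = pin[1]
        data[:, j] = thr + side * np.maximum(mag, 1e-9)

    events = pd.DataFrame(
        data, columns=channels,
        index=[f"event{i:06d}" for i in range(n_events)],
    )
    return events, pd.Series(truth_names, index=events.index, name="population")
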