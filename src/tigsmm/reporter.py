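"""Reporter-metabolite statistics.

A reporter metabolite is one whose neighboring enzyme-coding genes show
coordinated transcriptional change.  Gene-level two-sided p-values with a
direction of change are converted to one-tailed Z-scores for a chosen
direction (up or down):

    p_dir = p/2 if the gene moved in the direction of interest else 1 − p/2
    Z_g   = Φ⁻¹(1 − p_dir)

For a metabolite with gene neighborhood G (the union of GPR genes over
every reaction producing or consuming it, k = |G ∩ scored genes|):

    Z_raw = Σ_{g∈G} Z_g / √k

Z_raw is corrected against the background distribution of random size-k
gene sets drawn from all scored genes — exhaustively enumerated when
C(n, k) ≤ 10⁵, otherwise Monte-Carlo sampled with a fixed seed:

    Z_corrected = (Z_raw − μ_k) / σ_k,   p = 1 − Φ(Z_corrected)

A metabolite is a significant reporter in a direction when its
distinct-directional p-value falls below α (default 0.05, uncorrected).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from tigsmm.model_io import MetabolicModel

__all__ = [
    "GeneStat",
    "MetaboliteNeighborhood",
    "ReporterScore",
    "ReporterResult",
    "gene_zscore",
    "read_gene_stats",
    "write_gene_stats",
    "build_neighborhoods",
    "reporter_scores",
    "significant_reporters",
    "reporter_subnetwork",
]

_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16
_SIGMA_FLOOR = 1e-12
ENUMERATION_LIMIT = 10**5


@dataclass(frozen=True)
class GeneStat:
    """Two-sided p-value and direction of change for one gene."""

    gene_id: str
    p_value: float
    direction: str  # "up" | "down"

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(
                f"p-value for {self.gene_id!r} must be in (0, 1], got {self.p_value}"
            )
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")


@dataclass
class MetaboliteNeighborhood:
    """A metabolite and the genes of every reaction touching it."""

    metabolite_id: str
    genes: Set[str]


@dataclass
class ReporterScore:
    metabolite_id: str
    k: int
    z_raw_up: float
    z_corrected_up: float
    p_up: float
    z_raw_down: float
    z_corrected_down: float
    p_down: float


@dataclass
class ReporterResult:
    """Scores for every scorable metabolite, in input order."""

    scores: List[ReporterScore]
    n_scored_genes: int
    n_samples: int
    seed: Optional[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "metabolite_id": s.metabolite_id,
                    "k": s.k,
                    "z_raw_up": s.z_raw_up,
                    "z_corrected_up": s.z_corrected_up,
                    "p_up": s.p_up,
                    "z_raw_down": s.z_raw_down,
                    "z_corrected_down": s.z_corrected_down,
                    "p_down": s.p_down,
                }
                for s in self.scores
            ]
        )


def gene_zscore(stat: GeneStat, direction_of_interest: str = "up") -> float:
    """Directional Z-score from a two-sided p-value.

    The two-sided p is halved into the gene's own tail; if the gene moved
    against the direction of interest the one-tailed p is 1 − p/2, so
    strongly opposing genes get strongly negative Z.
    """
    if direction_of_interest not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction_of_interest!r}")
    p_dir = (
        stat.p_value / 2.0
        if stat.direction == direction_of_interest
        else 1.0 - stat.p_value / 2.0
    )
    p_dir = min(max(p_dir, _P_FLOOR), _P_CEIL)
    return float(stats.norm.ppf(1.0 - p_dir))


def read_gene_stats(path) -> List[GeneStat]:
    """Read a TSV with columns gene_id, p_value, direction."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "p_value", "direction"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return [
        GeneStat(gene_id=str(r.gene_id), p_value=float(r.p_value), direction=str(r.direction))
        for r in df.itertuples()
    ]


def write_gene_stats(stats_list: Sequence[GeneStat], path):
    pd.DataFrame(
        [
            {"gene_id": s.gene_id, "p_value": s.p_value, "direction": s.direction}
            for s in stats_list
        ]
    ).to_csv(path, sep="\t", index=False)
    return path


def build_neighborhoods(
    model: MetabolicModel, exclude: Iterable[str] = ()
) -> List[MetaboliteNeighborhood]:
    """Gene neighborhood of every metabolite: the union of GPR leaves over
    all reactions with a nonzero stoichiometric coefficient for it.
    Metabolites whose reactions all lack GPRs are not scorable and are
    omitted; ids in ``exclude`` (e.g. currency metabolites) are skipped."""
    excluded = set(exclude)
    genes_by_met: Dict[str, Set[str]] = {m.id: set() for m in model.metabolites}
    for rxn in model.reactions:
        rxn_genes = rxn.genes()
        if not rxn_genes:
            continue
        for met_id, coeff in rxn.stoich.items():
            if coeff != 0.0:
                genes_by_met[met_id] |= rxn_genes
    return [
        MetaboliteNeighborhood(metabolite_id=m.id, genes=genes_by_met[m.id])
        for m in model.metabolites
        if m.id not in excluded and genes_by_met[m.id]
    ]


def _sample_index_matrix(
    rng: np.random.Generator, n: int, k: int, n_samples: int
) -> np.ndarray:
    """(n_samples, k) matrix of distinct gene indices per row.

    Samples with replacement and resamples rows containing duplicates —
    cheap for k ≪ n, exact without-replacement distribution."""
    if k > n:
        raise ValueError(f"neighborhood size {k} exceeds scored-gene universe {n}")
    idx = rng.integers(0, n, size=(n_samples, k))
    while True:
        srt = np.sort(idx, axis=1)
        bad = (srt[:, 1:] == srt[:, :-1]).any(axis=1)
        if not bad.any():
            return idx
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), k))


def _background(
    z: np.ndarray,
    k: int,
    n_samples: int,
    rng: np.random.Generator,
    mode: str = "auto",
) -> Tuple[float, float]:
    """Mean and std of Z_raw for random size-k subsets of the scored genes.

    Exhaustive enumeration when C(n, k) is small enough, else sampling.
    """
    n = len(z)
    if mode == "auto":
        mode = "exact" if math.comb(n, k) <= ENUMERATION_LIMIT else "sample"
    if mode == "exact":
        sums = np.array(
            [sum(z[list(combo)]) for combo in itertools.combinations(range(n), k)]
        )
        vals = sums / math.sqrt(k)
    elif mode == "sample":
        idx = _sample_index_matrix(rng, n, k, n_samples)
        vals = z[idx].sum(axis=1) / math.sqrt(k)
    else:
        raise ValueError(f"unknown background mode {mode!r}")
    return float(vals.mean()), float(vals.std(ddof=0))


def reporter_scores(
    neighborhoods: Sequence[MetaboliteNeighborhood],
    gene_stats: Sequence[GeneStat],
    n_samples: int = 10_000,
    seed: Optional[int] = None,
    background: str = "auto",
) -> ReporterResult:
    """Score every neighborhood in both directions.

    Backgrounds are computed once per occurring k and direction from a
    single seeded generator, so identical seeds give identical results.
    Neighborhoods with no scored gene are skipped.
    """
    stats_by_gene = {s.gene_id: s for s in gene_stats}
    if len(stats_by_gene) != len(gene_stats):
        raise ValueError("duplicate gene ids in gene_stats")
    scored_genes = list(stats_by_gene)
    n = len(scored_genes)
    if n == 0:
        raise ValueError("no scored genes")
    gene_pos = {g: i for i, g in enumerate(scored_genes)}

    z_by_dir = {
        d: np.array([gene_zscore(stats_by_gene[g], d) for g in scored_genes])
        for d in ("up", "down")
    }

    ks = sorted(
        {
            len(nb.genes & stats_by_gene.keys())
            for nb in neighborhoods
            if nb.genes & stats_by_gene.keys()
        }
    )
    rng = np.random.default_rng(seed)
    bg: Dict[Tuple[str, int], Tuple[float, float]] = {}
    for d in ("up", "down"):
        for k in ks:
            bg[(d, k)] = _background(z_by_dir[d], k, n_samples, rng, mode=background)

    scores: List[ReporterScore] = []
    for nb in neighborhoods:
        members = sorted(nb.genes & stats_by_gene.keys())
        k = len(members)
        if k == 0:
            continue
        idx = [gene_pos[g] for g in members]
        per_dir = {}
        for d in ("up", "down"):
            z_raw = float(z_by_dir[d][idx].sum() / math.sqrt(k))
            mu, sigma = bg[(d, k)]
            z_corr = (z_raw - mu) / max(sigma, _SIGMA_FLOOR)
            p = float(stats.norm.sf(z_corr))
            p = min(max(p, _P_FLOOR), _P_CEIL)
            per_dir[d] = (z_raw, z_corr, p)
        scores.append(
            ReporterScore(
                metabolite_id=nb.metabolite_id,
                k=k,
                z_raw_up=per_dir["up"][0],
                z_corrected_up=per_dir["up"][1],
                p_up=per_dir["up"][2],
                z_raw_down=per_dir["down"][0],
                z_corrected_down=per_dir["down"][1],
                p_down=per_dir["down"][2],
            )
        )
    return ReporterResult(
        scores=scores, n_scored_genes=n, n_samples=n_samples, seed=seed
    )


def significant_reporters(
    result: ReporterResult, alpha: float = 0.05
) -> Dict[str, List[str]]:
    """Metabolites with a distinct-directional p below alpha, per
    direction; no multiple-testing correction."""
    return {
        "up": [s.metabolite_id for s in result.scores if s.p_up < alpha],
        "down": [s.metabolite_id for s in result.scores if s.p_down < alpha],
    }


def reporter_subnetwork(
    model: MetabolicModel, significant_ids: Iterable[str]
) -> List[Tuple[str, str]]:
    """Bipartite metabolite–reaction edge list induced by the significant
    metabolites and every reaction touching them."""
    wanted = set(significant_ids)
    unknown = wanted - set(model.metabolite_ids())
    if unknown:
        raise KeyError(f"metabolites not in model: {sorted(unknown)[:5]}")
    edges: List[Tuple[str, str]] = []
    for rxn in model.reactions:
        for met_id, coeff in rxn.stoich.items():
            if coeff != 0.0 and met_id in wanted:
                edges.append((met_id, rxn.id))
    return edges
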