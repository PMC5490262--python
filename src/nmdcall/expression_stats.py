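"""Expression-based validation: REV, group comparisons and the z-score.

REV (relative expression of variant) positions a mutant sample's expression
of a gene within a background built from samples of the same cancer (and
expression cluster, when labels exist) that carry no somatic mutation and no
copy-number call in that gene. With background size n and midrank R of the
mutant among background ∪ {mutant}, REV = R/(n+1) ∈ (0,1]; under the null it
is uniform on {k/(n+1)}, and low REV means depressed expression.

The gene-level z-score is the Mann-Whitney U statistic of the NMD-elicit
mutant group against wild type, normalised by N1·N2 — i.e. the tie-corrected
probability that a mutant sample out-expresses a wild-type one. z ≤ 0.3
marks an NMD-sensitive gene, 0.3 < z ≤ 0.4 intermediate, z > 0.4
insensitive; genes with fewer than three elicit mutants are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MIN_BACKGROUND_N = 8
MIN_MUTANTS = 3
TIER_SENSITIVE_MAX = 0.3
TIER_INTERMEDIATE_MAX = 0.4


@dataclass
class ExpressionTable:
    """Gene × sample log-scale expression with per-sample annotations."""

    values: pd.DataFrame  # index: genes, columns: samples
    sample_annotations: pd.DataFrame  # index: samples; columns: cancer[, cluster, msi]

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")
        missing = set(self.values.columns) - set(self.sample_annotations.index)
        if missing:
            raise ValueError(f"samples without annotation: {sorted(missing)[:5]}")

    @classmethod
    def from_tsv(cls, expr_path: str, annotations_path: str) -> "ExpressionTable":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        ann = pd.read_csv(annotations_path, sep="\t", index_col=0, dtype=str)
        return cls(values, ann)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class BackgroundSet:
    gene: str
    cancer: str
    expression_values: np.ndarray
    n: int
    reason: str = ""  # non-empty iff undefined

    @property
    def defined(self) -> bool:
        return not self.reason


@dataclass(frozen=True)
class RevResult:
    gene: str
    sample_id: str
    rank: float
    rev: float
    background_n: int


@dataclass(frozen=True)
class ZScoreResult:
    gene: str
    cancer: str
    n_wt: int
    n_mut: int
    u_wt: float
    u_mut: float
    z: float
    tier: str


def tier_for(z: float) -> str:
    """Sensitivity tier from a z-score (thresholds inclusive on the left)."""
    if z <= TIER_SENSITIVE_MAX:
        return "sensitive"
    if z <= TIER_INTERMEDIATE_MAX:
        return "intermediate"
    return "insensitive"


def build_background(
    gene: str,
    cancer: str,
    expr: ExpressionTable,
    mutated_pairs: Iterable[tuple[str, str]],
    cnv: pd.DataFrame | None = None,
    min_n: int = MIN_BACKGROUND_N,
    cluster: str | None = None,
) -> BackgroundSet:
    """Mutation- and CNV-free background expression for one gene and cancer.

    ``mutated_pairs`` are (gene, sample) pairs carrying *any* somatic
    mutation (all classes, pre-NMD filtering). When a cluster label is given
    the background is restricted to that cluster within the cancer.
    """
    if gene not in expr.values.index:
        return BackgroundSet(gene, cancer, np.array([]), 0, "gene not in matrix")
    ann = expr.sample_annotations
    mask = ann["cancer"] == cancer
    if cluster is not None and "cluster" in ann.columns:
        mask &= ann["cluster"] == cluster
    candidates = [s for s in expr.values.columns if mask.get(s, False)]
    mutated = {s for g, s in mutated_pairs if g == gene}
    candidates = [s for s in candidates if s not in mutated]
    if cnv is not None and gene in cnv.index:
        row = cnv.loc[gene]
        candidates = [s for s in candidates if s not in row.index or row[s] == 0]
    values = expr.values.loc[gene, candidates].to_numpy(dtype=float)
    if len(values) < min_n:
        return BackgroundSet(gene, cancer, values, len(values),
                             f"insufficient background (n={len(values)} < {min_n})")
    return BackgroundSet(gene, cancer, values, len(values))


def rev(mutant_value: float, background: BackgroundSet,
        sample_id: str = "") -> RevResult:
    """Midrank-based REV of one mutant value within its background."""
    if not background.defined:
        raise ValueError(f"undefined background: {background.reason}")
    bg = background.expression_values
    n_less = int(np.sum(bg < mutant_value))
    n_tied = int(np.sum(bg == mutant_value)) + 1  # including the mutant itself
    rank = n_less + (n_tied + 1) / 2.0
    return RevResult(background.gene, sample_id, rank,
                     rank / (background.n + 1), background.n)


def rev_group_compare(
    rev_a: Sequence[float],
    rev_b: Sequence[float],
    alternative: str = "less",
) -> dict:
    """Compare two REV groups (A hypothesised lower than B).

    Returns medians, their ratio, a Mann-Whitney p (exact for small
    tie-free groups, normal approximation with tie correction otherwise)
    and a Welch t-test p. Degenerate inputs (zero variance) are flagged.
    """
    a = np.asarray(rev_a, dtype=float)
    b = np.asarray(rev_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    out = {
        "median_a": med_a,
        "median_b": med_b,
        "ratio_of_medians": med_a / med_b if med_b != 0 else float("nan"),
        "degenerate": False,
    }
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]) or (a.size < 2 and b.size < 2):
        out.update(p_mww=float("nan"), p_ttest=float("nan"), degenerate=True)
        return out
    method = "exact" if (a.size + b.size <= 50
                         and len(np.unique(pooled)) == pooled.size) else "asymptotic"
    out["p_mww"] = float(stats.mannwhitneyu(a, b, alternative=alternative,
                                            method=method).pvalue)
    out["p_ttest"] = float(stats.ttest_ind(a, b, alternative=alternative,
                                           equal_var=False).pvalue)
    return out


def z_score(
    wt_values: Sequence[float],
    mut_values: Sequence[float],
    gene: str = "",
    cancer: str = "",
) -> ZScoreResult:
    """Normalised U statistic of mutants vs wild type, with sensitivity tier.

    Pooled midranks; U_mut = (rank sum of mutants) − N2(N2+1)/2 and
    z = U_mut/(N1·N2) ∈ [0, 1]. U_wt + U_mut == N1·N2 exactly.
    """
    wt = np.asarray(wt_values, dtype=float)
    mut = np.asarray(mut_values, dtype=float)
    n1, n2 = wt.size, mut.size
    if n2 < MIN_MUTANTS:
        raise ValueError(f"gene discarded: fewer than {MIN_MUTANTS} "
                         f"NMD-elicit mutants (n={n2})")
    if n1 < 1:
        raise ValueError("no wild-type samples")
    ranks = stats.rankdata(np.concatenate([wt, mut]))
    rank_sum_mut = float(ranks[n1:].sum())
    u_mut = rank_sum_mut - n2 * (n2 + 1) / 2.0
    u_wt = n1 * n2 - u_mut
    z = u_mut / (n1 * n2)
    return ZScoreResult(gene, cancer, n1, n2, u_wt, u_mut, z, tier_for(z))


# ---------------------------------------------------------------------------
# Batch drivers over a call table
# ---------------------------------------------------------------------------

def compute_rev_table(
    calls: pd.DataFrame,
    expr: ExpressionTable,
    mutated_pairs: Iterable[tuple[str, str]],
    cnv: pd.DataFrame | None = None,
    min_n: int = MIN_BACKGROUND_N,
) -> pd.DataFrame:
    """REV for every call whose gene/sample is in the expression matrix.

    Backgrounds are built per gene × cancer (× cluster when annotated) and
    cached. Calls without a defined background are reported with NaN REV and
    the reason.
    """
    ann = expr.sample_annotations
    pairs = list(mutated_pairs)
    cache: dict[tuple, BackgroundSet] = {}
    rows = []
    for row in calls.itertuples(index=False):
        gene, sample = row.gene, row.sample_id
        if gene not in expr.values.index or sample not in expr.values.columns:
            continue
        cancer = str(ann.loc[sample, "cancer"])
        cluster = (str(ann.loc[sample, "cluster"])
                   if "cluster" in ann.columns else None)
        key = (gene, cancer, cluster)
        if key not in cache:
            cache[key] = build_background(gene, cancer, expr, pairs, cnv,
                                          min_n, cluster)
        bg = cache[key]
        base = {"gene": gene, "sample_id": sample, "cancer": cancer,
                "nmd_class": getattr(row, "nmd_class", ""),
                "source_class": getattr(row, "source_class", ""),
                "background_n": bg.n}
        if not bg.defined:
            rows.append({**base, "rev": float("nan"), "reason": bg.reason})
            continue
        value = float(expr.values.loc[gene, sample])
        res = rev(value, bg, sample)
        rows.append({**base, "rev": res.rev, "reason": ""})
    return pd.DataFrame(
        rows, columns=["gene", "sample_id", "cancer", "nmd_class",
                       "source_class", "background_n", "rev", "reason"])


def compute_z_scores(
    calls: pd.DataFrame,
    expr: ExpressionTable,
    mutated_pairs: Iterable[tuple[str, str]],
    cnv: pd.DataFrame | None = None,
    min_n: int = 1,
) -> pd.DataFrame:
    """Per gene × cancer z-score over NMD-elicit mutants vs clean wild type."""
    ann = expr.sample_annotations
    pairs = list(mutated_pairs)
    elicit = calls[calls["nmd_class"] == "elicit"]
    rows = []
    for (gene, cancer), grp in _group_by_gene_cancer(elicit, ann):
        if gene not in expr.values.index:
            continue
        mut_samples = sorted({s for s in grp if s in expr.values.columns})
        if len(mut_samples) < MIN_MUTANTS:
            rows.append({"gene": gene, "cancer": cancer, "n_wt": 0,
                         "n_mut": len(mut_samples), "z": float("nan"),
                         "tier": "", "reason": "fewer than 3 elicit mutants"})
            continue
        bg = build_background(gene, cancer, expr, pairs, cnv, min_n)
        if not bg.defined or bg.n < 1:
            rows.append({"gene": gene, "cancer": cancer, "n_wt": bg.n,
                         "n_mut": len(mut_samples), "z": float("nan"),
                         "tier": "", "reason": bg.reason or "no wild type"})
            continue
        mut_values = expr.values.loc[gene, mut_samples].to_numpy(dtype=float)
        res = z_score(bg.expression_values, mut_values, gene, cancer)
        rows.append({"gene": gene, "cancer": cancer, "n_wt": res.n_wt,
                     "n_mut": res.n_mut, "z": res.z, "tier": res.tier,
                     "reason": ""})
    return pd.DataFrame(rows, columns=["gene", "cancer", "n_wt", "n_mut",
                                       "z", "tier", "reason"])


def _group_by_gene_cancer(calls: pd.DataFrame, ann: pd.DataFrame):
    groups: dict[tuple[str, str], set[str]] = {}
    for row in calls.itertuples(index=False):
        if row.sample_id not in ann.index:
            continue
        cancer = str(ann.loc[row.sample_id, "cancer"])
        groups.setdefault((row.gene, cancer), set()).add(row.sample_id)
    return sorted(groups.items())
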