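"""Cohort-level analyses: hypermutation enrichment, gene sets, TSG burden.

Hypermutated samples carry more than 1,000 filtered somatic mutations,
non-hypermutated fewer than 100; the band in between is excluded. Per-gene
enrichment of NMD-elicit over silent-class mutations in the hypermutated
stratum is scored by a double-quotient normalised ratio (each count divided
by its cohort-wide stratum total, with ½ pseudo-counts) and a two-sided
Fisher exact test with Benjamini-Hochberg correction across genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

HYPER_MIN = 1000  # strictly more than this many filtered mutations
NONHYPER_MAX = 100  # strictly fewer

#: variant classes counted as the silent reference stratum
SILENT_CLASSES = frozenset({"Silent", "3'UTR", "5'UTR", "Intron", "RNA"})


@dataclass(frozen=True)
class HypermutationLabel:
    sample_id: str
    n_filtered_mutations: int
    label: str  # hyper | non_hyper | excluded


@dataclass(frozen=True)
class EnrichmentResult:
    gene: str
    a: int  # NMD-elicit in hyper
    b: int  # silent-class in hyper
    c: int  # NMD-elicit in non-hyper
    d: int  # silent-class in non-hyper
    normalized_ratio: float
    fisher_p: float
    fdr: float


@dataclass(frozen=True)
class GeneSetResult:
    set_name: str
    overlap: int
    set_size: int
    universe_size: int
    hit_count: int
    p: float
    fdr: float


def label_hypermutation(
    per_sample_counts: Mapping[str, int]
) -> list[HypermutationLabel]:
    """Label samples hyper (>1000), non_hyper (<100) or excluded."""
    labels = []
    for sample, n in sorted(per_sample_counts.items()):
        if n > HYPER_MIN:
            lab = "hyper"
        elif n < NONHYPER_MAX:
            lab = "non_hyper"
        else:
            lab = "excluded"
        labels.append(HypermutationLabel(sample, int(n), lab))
    return labels


def _is_silent(source_class: str) -> bool:
    return str(source_class).replace("′", "'") in SILENT_CLASSES


def enrichment_per_gene(
    mutations: pd.DataFrame,
    labels: Sequence[HypermutationLabel],
    count_samples: bool = False,
) -> pd.DataFrame:
    """Per-gene NMD-elicit vs silent enrichment across hypermutation strata.

    ``mutations`` needs columns gene, sample_id, source_class and nmd_class
    (nmd_class may be empty/NaN for mutations never classified, e.g. UTR
    records retained for silent counting). Counts are mutation events by
    default; ``count_samples`` switches to distinct mutated samples.

    The normalised ratio divides each stratum's elicit:silent quotient by
    the cohort-wide totals of each type in that stratum (½ pseudo-counts
    throughout), cancelling negative selection on NMD-elicit mutations:
    ((a+½)/(A_h+½)) / ((b+½)/(S_h+½)) ÷ [((c+½)/(A_n+½)) / ((d+½)/(S_n+½))].
    """
    label_map = {l.sample_id: l.label for l in labels}
    df = mutations.copy()
    df["stratum"] = df["sample_id"].map(label_map)
    df = df[df["stratum"].isin(["hyper", "non_hyper"])]
    df["is_elicit"] = df["nmd_class"].astype(str) == "elicit"
    df["is_silent"] = df["source_class"].map(_is_silent)

    def _count(sub: pd.DataFrame, flag: str) -> dict[str, int]:
        sel = sub[sub[flag]]
        if count_samples:
            return sel.groupby("gene")["sample_id"].nunique().to_dict()
        return sel.groupby("gene").size().to_dict()

    hyper = df[df["stratum"] == "hyper"]
    nonhyper = df[df["stratum"] == "non_hyper"]
    a_map, b_map = _count(hyper, "is_elicit"), _count(hyper, "is_silent")
    c_map, d_map = _count(nonhyper, "is_elicit"), _count(nonhyper, "is_silent")
    A_h, S_h = sum(a_map.values()), sum(b_map.values())
    A_n, S_n = sum(c_map.values()), sum(d_map.values())

    genes = sorted(set(df["gene"]))
    rows = []
    for g in genes:
        a, b = a_map.get(g, 0), b_map.get(g, 0)
        c, d = c_map.get(g, 0), d_map.get(g, 0)
        hyper_q = ((a + 0.5) / (A_h + 0.5)) / ((b + 0.5) / (S_h + 0.5))
        non_q = ((c + 0.5) / (A_n + 0.5)) / ((d + 0.5) / (S_n + 0.5))
        ratio = hyper_q / non_q
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        rows.append({"gene": g, "a": a, "b": b, "c": c, "d": d,
                     "normalized_ratio": ratio, "fisher_p": p})
    out = pd.DataFrame(rows, columns=["gene", "a", "b", "c", "d",
                                      "normalized_ratio", "fisher_p"])
    if not out.empty:
        out["fdr"] = multipletests(out["fisher_p"], method="fdr_bh")[1]
    else:
        out["fdr"] = []
    return out


def read_gmt(path: str) -> dict[str, list[str]]:
    """Standard GMT: set name, description, then member genes, tab-separated."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def geneset_overrepresentation(
    significant_genes: Iterable[str],
    universe: Iterable[str],
    gmt_path: str,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each GMT set."""
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty gene universe")
    hits = set(significant_genes) & universe_set
    rows = []
    for name, members in read_gmt(gmt_path).items():
        members_in = set(members) & universe_set
        overlap = len(members_in & hits)
        # P(X >= overlap), X ~ Hypergeom(M=|universe|, n=|hits|, N=|set|)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe_set),
                                     len(hits), len(members_in)))
        rows.append({"set_name": name, "overlap": overlap,
                     "set_size": len(members_in),
                     "universe_size": len(universe_set),
                     "hit_count": len(hits), "p": p})
    out = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size",
                                      "universe_size", "hit_count", "p"])
    if not out.empty:
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["fdr"] = []
    return out


def tsg_burden(
    calls: pd.DataFrame,
    tsg_list: Iterable[str],
    sample_annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Per-cancer fraction of samples with ≥1 NMD-elicit mutation in a TSG.

    The denominator is every annotated sample of the cancer; a sample with
    several elicit TSG mutations counts once. A pooled 'ALL' row is added.
    """
    tsgs = set(tsg_list)
    if not tsgs:
        raise ValueError("empty TSG list")
    elicit = calls[(calls["nmd_class"] == "elicit") & calls["gene"].isin(tsgs)]
    hit_samples = set(elicit["sample_id"])
    rows = []
    total_num = total_den = 0
    for cancer, grp in sample_annotations.groupby("cancer"):
        samples = set(grp.index)
        num = len(samples & hit_samples)
        rows.append({"cancer": cancer, "n_samples": len(samples),
                     "n_with_elicit_tsg": num,
                     "fraction": num / len(samples) if samples else 0.0})
        total_num += num
        total_den += len(samples)
    rows.append({"cancer": "ALL", "n_samples": total_den,
                 "n_with_elicit_tsg": total_num,
                 "fraction": total_num / total_den if total_den else 0.0})
    return pd.DataFrame(rows, columns=["cancer", "n_samples",
                                       "n_with_elicit_tsg", "fraction"])


def deletion_cooccurrence(
    calls: pd.DataFrame,
    cnv: pd.DataFrame,
    rev_table: pd.DataFrame | None = None,
    deletion_threshold: int = -1,
) -> tuple[pd.DataFrame, dict]:
    """Association of NMD-elicit mutations with locus deletions.

    Per gene, a 2×2 Fisher test of elicit-mutation presence × deletion
    presence (CNV ≤ ``deletion_threshold``) across the CNV-profiled samples.
    When a REV table is supplied, the REVs of elicit mutants with vs without
    a co-deletion are compared by one-sided Mann-Whitney (co-deleted
    hypothesised lower); degenerate strata are flagged.
    """
    samples = list(cnv.columns)
    elicit = calls[calls["nmd_class"] == "elicit"]
    elicit_pairs = set(zip(elicit["gene"], elicit["sample_id"]))
    rows = []
    for gene in sorted(set(elicit["gene"]) & set(cnv.index)):
        deleted = cnv.loc[gene] <= deletion_threshold
        a = b = c = d = 0
        for s in samples:
            has_mut = (gene, s) in elicit_pairs
            has_del = bool(deleted.get(s, False))
            if has_mut and has_del:
                a += 1
            elif has_mut:
                b += 1
            elif has_del:
                c += 1
            else:
                d += 1
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        rows.append({"gene": gene, "mut_del": a, "mut_nodel": b,
                     "nomut_del": c, "nomut_nodel": d, "fisher_p": p})
    table = pd.DataFrame(rows, columns=["gene", "mut_del", "mut_nodel",
                                        "nomut_del", "nomut_nodel", "fisher_p"])
    if not table.empty:
        table["fdr"] = multipletests(table["fisher_p"], method="fdr_bh")[1]
    else:
        table["fdr"] = []

    strat: dict = {"degenerate": True, "p_mww": float("nan"),
                   "n_with_deletion": 0, "n_without_deletion": 0}
    if rev_table is not None and not rev_table.empty:
        rev_e = rev_table[rev_table["nmd_class"] == "elicit"].dropna(subset=["rev"])
        with_del, without_del = [], []
        for row in rev_e.itertuples(index=False):
            if row.gene not in cnv.index or row.sample_id not in cnv.columns:
                continue
            if cnv.loc[row.gene, row.sample_id] <= deletion_threshold:
                with_del.append(row.rev)
            else:
                without_del.append(row.rev)
        strat["n_with_deletion"] = len(with_del)
        strat["n_without_deletion"] = len(without_del)
        if with_del and without_del:
            strat["degenerate"] = False
            strat["p_mww"] = float(stats.mannwhitneyu(
                with_del, without_del, alternative="less").pvalue)
            strat["median_with_deletion"] = float(np.median(with_del))
            strat["median_without_deletion"] = float(np.median(without_del))
    return table, strat
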