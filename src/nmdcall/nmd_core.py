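"""The NMD classifier: mutate the CDS, relocate the ORF, apply the rules.

For each kept mutation the spliced CDS is edited, exon-junction offsets are
recomputed in mutated coordinates, the most-upstream start codon defines the
putative ORF, and the first in-frame stop codon is located. A stop is a
premature termination codon (PTC) iff its third base is not the final base
of the mutated sequence. A PTC elicits NMD when all three positional rules
hold:

* the gene has at least two (coding) exons;
* the PTC lies more than ``junction_min_bp`` (default 50) nt upstream of the
  last exon-exon junction, measured from the base after the stop codon;
* the PTC lies more than ``start_min_bp`` (default 200) nt downstream of the
  start codon, measured first base to first base.

Otherwise a PTC-bearing variant escapes NMD; variants without a PTC
(including start-codon loss with no rescue ORF and nonstop variants) are
non_ptc.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genemodel_io import GeneModel
from .mutation_io import CdsMutation

DEFAULT_STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class NmdConfig:
    """Tunable thresholds of the classifier.

    ``junction_min_bp``/``start_min_bp`` are strict lower bounds ("more
    than"). ``start_codons`` defaults to the canonical initiator only;
    alternative starts (e.g. ATA) can be added.
    """

    junction_min_bp: int = 50
    start_min_bp: int = 200
    start_codons: tuple[str, ...] = ("ATG",)
    stop_codons: tuple[str, ...] = DEFAULT_STOP_CODONS
    combine_sample_mutations: bool = False


DEFAULT_CONFIG = NmdConfig()


@dataclass(frozen=True)
class MutatedSequence:
    sequence: str
    junction_offsets: tuple[int, ...]
    shift: int  # len(alt) - len(ref)


@dataclass(frozen=True)
class NMDCall:
    gene: str
    sample_id: str
    source_class: str
    nmd_class: str  # elicit | escape | non_ptc
    start_offset: int | None
    ptc_start: int | None
    d_start: int | None
    d_junction: int | None
    rule_multi_exon: bool
    rule_junction: bool
    rule_startdist: bool
    flags: tuple[str, ...] = ()


def _edit(seq: str, junctions: Sequence[int], mut: CdsMutation) -> MutatedSequence:
    p = mut.cds_pos
    if mut.mut_type == "ins":
        new = seq[: p + 1] + mut.alt + seq[p + 1 :]
        shift = len(mut.alt)
        edit_point = p
    else:
        if seq[p : p + len(mut.ref)] != mut.ref:
            raise ValueError(
                f"{mut.gene}: ref {mut.ref!r} does not match CDS at {p} "
                f"({seq[p:p + len(mut.ref)]!r})"
            )
        new = seq[:p] + mut.alt + seq[p + len(mut.ref) :]
        shift = len(mut.alt) - len(mut.ref)
        edit_point = p
    new_j = tuple(j if j <= edit_point else j + shift for j in junctions)
    return MutatedSequence(new, new_j, shift)


def apply_mutation(model: GeneModel, mut: CdsMutation) -> MutatedSequence:
    """Edit the spliced CDS and recompute junction offsets.

    Junction offsets strictly downstream of the edit point move by
    ``len(alt) - len(ref)``; deletions crossing a junction are excluded
    upstream (single-exon footprint filter), so no offset is ever consumed.
    """
    return _edit(model.cds_sequence, model.junction_offsets, mut)


def find_orf(
    seq: str,
    start_codons: Iterable[str] = ("ATG",),
    stop_codons: Iterable[str] = DEFAULT_STOP_CODONS,
) -> tuple[int | None, int | None, bool]:
    """Locate the putative ORF in a (mutated) CDS.

    Returns (start_offset, ptc_start, terminated): the most upstream start
    codon anywhere in the sequence, the first in-frame stop scanning
    triplets from it, and whether translation terminates before the
    sequence runs out.
    """
    starts = set(start_codons)
    stops = set(stop_codons)
    start_offset = None
    for i in range(len(seq) - 2):
        if seq[i : i + 3] in starts:
            start_offset = i
            break
    if start_offset is None:
        return None, None, False
    for i in range(start_offset, len(seq) - 2, 3):
        if seq[i : i + 3] in stops:
            return start_offset, i, True
    return start_offset, None, False


def evaluate_rules(
    n_exons: int,
    d_start: int,
    d_junction: int | None,
    config: NmdConfig = DEFAULT_CONFIG,
) -> tuple[bool, bool, bool]:
    """The three positional rules, with strict thresholds.

    Returns (rule_multi_exon, rule_junction, rule_startdist). ``d_junction``
    is None for single-exon genes, failing the junction rule.
    """
    rule_multi_exon = n_exons >= 2
    rule_junction = d_junction is not None and d_junction > config.junction_min_bp
    rule_startdist = d_start > config.start_min_bp
    return rule_multi_exon, rule_junction, rule_startdist


def classify(
    model: GeneModel, mut: CdsMutation, config: NmdConfig = DEFAULT_CONFIG
) -> NMDCall:
    """Classify one mutation as NMD-elicit, NMD-escape or non_ptc."""
    mseq = apply_mutation(model, mut)
    return _classify_sequence(mseq, model.n_exons, mut.gene, mut.sample_id,
                              mut.source_class, config)


def _classify_sequence(
    mseq: MutatedSequence,
    n_exons: int,
    gene: str,
    sample_id: str,
    source_class: str,
    config: NmdConfig,
) -> NMDCall:
    start, ptc_start, terminated = find_orf(
        mseq.sequence, config.start_codons, config.stop_codons
    )
    flags: list[str] = []
    if start is None:
        return NMDCall(gene, sample_id, source_class, "non_ptc", None, None,
                       None, None, False, False, False, ("no_start_codon",))
    if start > 0:
        flags.append("start_relocated")
    if not terminated:
        flags.append("nonstop")
        return NMDCall(gene, sample_id, source_class, "non_ptc", start, None,
                       None, None, False, False, False, tuple(flags))
    ptc_end = ptc_start + 2
    if ptc_end == len(mseq.sequence) - 1:
        # stop coincides with the end of the annotated CDS: not premature
        return NMDCall(gene, sample_id, source_class, "non_ptc", start, None,
                       None, None, False, False, False, tuple(flags))
    d_start = ptc_start - start
    last_junction = mseq.junction_offsets[-1] if mseq.junction_offsets else None
    d_junction = None if last_junction is None else last_junction - (ptc_end + 1)
    r_exon, r_junc, r_start = evaluate_rules(n_exons, d_start, d_junction, config)
    nmd_class = "elicit" if (r_exon and r_junc and r_start) else "escape"
    return NMDCall(gene, sample_id, source_class, nmd_class, start, ptc_start,
                   d_start, d_junction, r_exon, r_junc, r_start, tuple(flags))


def classify_batch(
    models: Mapping[str, GeneModel],
    mutations: Sequence[CdsMutation],
    config: NmdConfig = DEFAULT_CONFIG,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify a batch; returns the call table and the class cross-tab.

    In the default mode every mutation is classified independently against
    the wild-type CDS. With ``config.combine_sample_mutations`` all kept
    mutations of one gene in one sample are applied jointly (descending
    cds_pos, so upstream coordinates stay valid) and one call is emitted per
    gene+sample with the source classes joined by ';'.
    """
    calls: list[NMDCall] = []
    if config.combine_sample_mutations:
        groups: dict[tuple[str, str], list[CdsMutation]] = {}
        for m in mutations:
            groups.setdefault((m.gene, m.sample_id), []).append(m)
        for (gene, sample), muts in groups.items():
            model = models[gene]
            mseq = MutatedSequence(model.cds_sequence, model.junction_offsets, 0)
            for m in sorted(muts, key=lambda x: -x.cds_pos):
                mseq = _edit(mseq.sequence, mseq.junction_offsets, m)
            src = ";".join(sorted({m.source_class for m in muts}))
            calls.append(_classify_sequence(mseq, model.n_exons, gene, sample,
                                            src, config))
    else:
        for m in mutations:
            calls.append(classify(models[m.gene], m, config))

    table = calls_to_frame(calls)
    if table.empty:
        crosstab = pd.DataFrame()
    else:
        crosstab = pd.crosstab(table["source_class"], table["nmd_class"])
    return table, crosstab


def calls_to_frame(calls: Sequence[NMDCall]) -> pd.DataFrame:
    cols = ["gene", "sample_id", "source_class", "nmd_class", "start_offset",
            "ptc_start", "d_start", "d_junction", "rule_multi_exon",
            "rule_junction", "rule_startdist", "flags"]
    rows = [
        {**{c: getattr(c_, c) for c in cols[:-1]}, "flags": ",".join(c_.flags)}
        for c_ in calls
    ]
    return pd.DataFrame(rows, columns=cols)
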