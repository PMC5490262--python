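"""Seeded generators for every input the toolkit consumes, plus the oracle.

The generators emulate a tiny tumour-sequencing study: multi-exon genes
with clean ORFs on synthetic contigs (FASTA + GTF), somatic mutation
catalogues (MAF) with ground-truth NMD labels, and log-scale expression
matrices in which NMD-elicit mutants are shifted down by a configurable
effect size. Ground-truth classes come from :func:`oracle_classify`, a
deliberately naive re-derivation of the classification rules that shares no
code with :mod:`nmdcall.nmd_core`.

A single integer seed drives everything through fixed `numpy` substreams
(spawned as ``default_rng([seed, k])`` with k = 0 random genes, 1 boundary
constructs, 2 mutations, 3 expression, 4 enrichment cohort), so every
output is reproducible across platforms.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genemodel_io import GeneModel, build_gene_model, revcomp
from .mutation_io import CdsMutation, lift_back

STOPS = ("TAA", "TAG", "TGA")
BASES = "ACGT"
_ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
NON_STOP_CODONS = [c for c in _ALL_CODONS if c not in STOPS]

MAF_COLUMNS = ["Hugo_Symbol", "Chromosome", "Start_Position", "End_Position",
               "Reference_Allele", "Tumor_Seq_Allele2",
               "Variant_Classification", "Tumor_Sample_Barcode"]

_CLASS_OF_TYPE = {
    "nonsense_snv": "Nonsense_Mutation",
    "missense": "Missense_Mutation",
    "silent": "Silent",
    "frameshift_del": "Frame_Shift_Del",
    "frameshift_ins": "Frame_Shift_Ins",
    "inframe_del": "In_Frame_Del",
    "startloss": "Translation_Start_Site",
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults give a small but structurally realistic cohort: genes of 1-6
    coding exons of 90-300 nt, 60 samples, a mutation catalogue dominated by
    point mutations with a sizeable indel fraction, and an NMD effect of two
    background standard deviations on the expression of elicit mutants.
    """

    seed: int = 0
    n_genes: int = 20
    exon_count_range: tuple[int, int] = (1, 6)
    exon_length_range: tuple[int, int] = (90, 300)
    n_samples: int = 60
    n_mutations: int = 300
    mutation_mix: dict = field(default_factory=lambda: {
        "nonsense_snv": 0.20, "frameshift_del": 0.15, "frameshift_ins": 0.15,
        "inframe_del": 0.10, "missense": 0.15, "silent": 0.20,
        "startloss": 0.05,
    })
    nmd_effect_size: float = 2.0  # downward shift in background-SD units
    background_noise_sd: float = 1.0
    fraction_hyper: float = 0.1
    planted_enriched_genes: list = field(default_factory=list)
    codeletion_fraction: float = 0.0
    codeletion_shift: float = 0.0
    include_boundary_genes: bool = True
    plant_filter_cases: bool = True

    def __post_init__(self) -> None:
        total = sum(self.mutation_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mutation_mix proportions sum to {total}, not 1")
        for lo, hi in (self.exon_count_range, self.exon_length_range):
            if lo <= 0 or hi < lo:
                raise ValueError("ranges must be positive and ordered")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


# ---------------------------------------------------------------------------
# The independent brute-force oracle
# ---------------------------------------------------------------------------

def oracle_classify(
    cds: str,
    junctions: list[int],
    mutation: CdsMutation,
    junction_min_bp: int = 50,
    start_min_bp: int = 200,
    start_codons: tuple[str, ...] = ("ATG",),
) -> str:
    """Naive re-derivation of the NMD call: string edit, scan, rule check.

    Returns 'elicit', 'escape' or 'non_ptc'. Works from raw inputs only.
    """
    p = mutation.cds_pos
    if mutation.mut_type == "ins":
        seq = cds[: p + 1] + mutation.alt + cds[p + 1 :]
        shift = len(mutation.alt)
    else:
        if cds[p : p + len(mutation.ref)] != mutation.ref:
            raise ValueError("oracle: ref mismatch")
        seq = cds[:p] + mutation.alt + cds[p + len(mutation.ref) :]
        shift = len(mutation.alt) - len(mutation.ref)
    juncs = [j + shift if j > p else j for j in junctions]

    start = None
    for i in range(len(seq) - 2):
        if seq[i : i + 3] in start_codons:
            start = i
            break
    if start is None:
        return "non_ptc"
    stop = None
    for i in range(start, len(seq) - 2, 3):
        if seq[i : i + 3] in STOPS:
            stop = i
            break
    if stop is None:
        return "non_ptc"
    if stop + 3 == len(seq):
        return "non_ptc"  # terminates at the annotated end: not premature
    n_exons = len(junctions) + 1
    elicit = (
        n_exons >= 2
        and len(juncs) > 0
        and (max(juncs) - (stop + 3)) > junction_min_bp
        and (stop - start) > start_min_bp
    )
    return "elicit" if elicit else "escape"


# ---------------------------------------------------------------------------
# Gene construction
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + non-stop body + one terminal stop: always passes wild-type QC."""
    body = rng.choice(NON_STOP_CODONS, size=n_codons - 2)
    return "ATG" + "".join(body) + str(rng.choice(STOPS))


def _assemble_gene(
    gene_id: str,
    transcript_id: str,
    contig: str,
    strand: str,
    cds: str,
    junction_offsets: list[int],
    rng: np.random.Generator,
) -> tuple[GeneModel, str]:
    """Place a spliced CDS on a fresh contig; returns (model, contig_seq)."""
    bounds = [0, *junction_offsets, len(cds)]
    chunks = [cds[a:b] for a, b in zip(bounds, bounds[1:])]  # translation order
    if strand == "-":
        genomic_chunks = [revcomp(c) for c in reversed(chunks)]
    else:
        genomic_chunks = chunks
    flank5 = int(rng.integers(50, 150))
    introns = [int(rng.integers(60, 200)) for _ in range(len(chunks) - 1)]
    pieces, intervals, pos = [], [], 0

    def _rand_seq(n: int) -> str:
        return "".join(rng.choice(list(BASES), size=n))

    pieces.append(_rand_seq(flank5))
    pos += flank5
    for i, chunk in enumerate(genomic_chunks):
        intervals.append((pos, pos + len(chunk)))
        pieces.append(chunk)
        pos += len(chunk)
        if i < len(introns):
            pieces.append(_rand_seq(introns[i]))
            pos += introns[i]
    pieces.append(_rand_seq(int(rng.integers(50, 150))))
    contig_seq = "".join(pieces)
    model = build_gene_model(gene_id, transcript_id, contig, strand,
                             intervals, {contig: contig_seq})
    assert model.cds_sequence == cds and list(model.junction_offsets) == list(
        junction_offsets
    )
    return model, contig_seq


def _random_gene(
    gene_id: str, contig: str, rng: np.random.Generator, config: SimConfig
) -> tuple[GeneModel, str]:
    lo_c, hi_c = config.exon_count_range
    lo_l, hi_l = config.exon_length_range
    n_exons = int(rng.integers(lo_c, hi_c + 1))
    lengths = [int(rng.integers(lo_l, hi_l + 1)) for _ in range(n_exons)]
    total = sum(lengths)
    lengths[-1] += (3 - total % 3) % 3  # keep CDS a codon multiple
    total = sum(lengths)
    cds = _random_cds(rng, total // 3)
    offsets, acc = [], 0
    for ln in lengths[:-1]:
        acc += ln
        offsets.append(acc)
    strand = "+" if rng.random() < 0.5 else "-"
    return _assemble_gene(gene_id, gene_id + ".t1", contig, strand, cds,
                          offsets, rng)


# ---------------------------------------------------------------------------
# Targeted boundary constructs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundaryCase:
    name: str
    model: GeneModel
    contig_seq: str
    mutation: CdsMutation
    expected_class: str
    expected_d_start: int | None = None
    expected_d_junction: int | None = None


def _planted_cds(rng, n_codons: int, planted: dict[int, str]) -> str:
    codons = ["ATG"] + list(rng.choice(NON_STOP_CODONS, size=n_codons - 2)) + ["TAA"]
    for idx, codon in planted.items():
        codons[idx] = codon
    return "".join(codons)


def boundary_constructs(config: SimConfig) -> list[BoundaryCase]:
    """Purpose-built genes probing the strict rule thresholds.

    The junction-distance pair sits exactly at 50 (escape) and 51 (elicit)
    nt. Because the PTC is found by in-frame scanning, the start distance is
    always a codon multiple; the start-distance constructs therefore use the
    codon-aligned values 174 and 198 (both escape, the near-miss failure
    mode just under the 200-nt threshold) and 201 (elicit). Also included:
    a single-exon PTC, a silent substitution, a nonstop substitution, a
    start-codon loss and an in-frame deletion that juxtaposes a new stop.
    """
    rng = config.rng(1)
    cases: list[BoundaryCase] = []

    def snv(gene, pos, ref, alt, klass):
        return CdsMutation(gene, "BSAMPLE", pos, ref, alt, "snv", klass)

    # -- d_junction boundary pair: PTC at codon 100 (offset 300)
    for name, junction, strand, expect in (
        ("djunction_50", 353, "+", "escape"),
        ("djunction_51", 354, "-", "elicit"),
    ):
        gene = "BND_" + name.upper()
        cds = _planted_cds(rng, 151, {100: "TAC"})
        model, seq = _assemble_gene(gene, gene + ".t1", "c_" + name, strand,
                                    cds, [junction], rng)
        cases.append(BoundaryCase(
            name, model, seq,
            snv(gene, 302, "C", "A", "Nonsense_Mutation"),  # TAC -> TAA
            expect, expected_d_start=300,
            expected_d_junction=junction - 303))

    # -- d_start constructs: junction at 300, PTC at codon k
    for name, codon_idx, expect in (
        ("dstart_174", 58, "escape"),
        ("dstart_198", 66, "escape"),
        ("dstart_201", 67, "elicit"),
    ):
        gene = "BND_" + name.upper()
        cds = _planted_cds(rng, 151, {codon_idx: "TAC"})
        model, seq = _assemble_gene(gene, gene + ".t1", "c_" + name, "+",
                                    cds, [300], rng)
        pos = 3 * codon_idx
        cases.append(BoundaryCase(
            name, model, seq, snv(gene, pos + 2, "C", "A", "Nonsense_Mutation"),
            expect, expected_d_start=pos,
            expected_d_junction=300 - (pos + 3)))

    # -- single-exon gene with a deep internal PTC: fails the exon rule
    gene = "BND_SINGLE_EXON"
    cds = _planted_cds(rng, 200, {100: "TAC"})
    model, seq = _assemble_gene(gene, gene + ".t1", "c_single", "+", cds, [], rng)
    cases.append(BoundaryCase(
        "single_exon_ptc", model, seq,
        snv(gene, 302, "C", "A", "Nonsense_Mutation"), "escape",
        expected_d_start=300, expected_d_junction=None))

    # -- silent wobble substitution: GGC -> GGA (Gly), stop stays terminal
    gene = "BND_SILENT"
    cds = _planted_cds(rng, 151, {50: "GGC"})
    model, seq = _assemble_gene(gene, gene + ".t1", "c_silent", "+", cds,
                                [300], rng)
    cases.append(BoundaryCase(
        "silent", model, seq, snv(gene, 152, "C", "A", "Silent"), "non_ptc"))

    # -- nonstop: terminal TAA -> AAA leaves no in-frame stop at all
    gene = "BND_NONSTOP"
    cds = _planted_cds(rng, 151, {})
    model, seq = _assemble_gene(gene, gene + ".t1", "c_nonstop", "+", cds,
                                [300], rng)
    L = len(cds)
    cases.append(BoundaryCase(
        "nonstop", model, seq,
        snv(gene, L - 3, "T", "A", "Nonstop_Mutation"), "non_ptc"))

    # -- start-codon loss: ATG -> AAG; class depends on the rescue ORF
    gene = "BND_STARTLOSS"
    cds = _planted_cds(rng, 151, {})
    model, seq = _assemble_gene(gene, gene + ".t1", "c_startloss", "+", cds,
                                [300], rng)
    mut = snv(gene, 1, "T", "A", "Translation_Start_Site")
    expect = oracle_classify(cds, [300], mut)
    cases.append(BoundaryCase("startloss", model, seq, mut, expect))

    # -- in-frame deletion juxtaposing T|GA into TGA at codon 100
    gene = "BND_INFRAME_DEL"
    cds = _planted_cds(rng, 200, {100: "TGC", 101: "GAA"})
    model, seq = _assemble_gene(gene, gene + ".t1", "c_ifdel", "+", cds,
                                [450], rng)
    mut = CdsMutation(gene, "BSAMPLE", 302, "CGA", "", "del", "In_Frame_Del")
    cases.append(BoundaryCase(
        "inframe_del_ptc", model, seq, mut, "elicit",
        expected_d_start=300, expected_d_junction=447 - 303))

    for case in cases:  # every construct must agree with the oracle
        got = oracle_classify(case.model.cds_sequence,
                              list(case.model.junction_offsets), case.mutation)
        if got != case.expected_class:
            raise AssertionError(
                f"boundary construct {case.name}: oracle says {got}, "
                f"expected {case.expected_class}")
    return cases


# ---------------------------------------------------------------------------
# Genome / annotation output
# ---------------------------------------------------------------------------

def generate_genes(config: SimConfig) -> tuple[list[GeneModel], dict[str, str]]:
    """All synthetic gene models plus their contig sequences."""
    rng = config.rng(0)
    models, contigs = [], {}
    for i in range(config.n_genes):
        gene_id = f"GENE{i + 1:04d}"
        contig = f"chrS{i + 1}"
        model, seq = _random_gene(gene_id, contig, rng, config)
        models.append(model)
        contigs[contig] = seq
    if config.include_boundary_genes:
        for case in boundary_constructs(config):
            models.append(case.model)
            contigs[case.model.chromosome] = case.contig_seq
    return models, contigs


def simulate_genome(config: SimConfig, outdir: str) -> tuple[str, str]:
    """Write the synthetic genome (FASTA) and gene models (GTF)."""
    models, contigs = generate_genes(config)
    os.makedirs(outdir, exist_ok=True)
    fasta_path = os.path.join(outdir, "genome.fa")
    gtf_path = os.path.join(outdir, "genes.gtf")
    with open(fasta_path, "w") as fh:
        for name in contigs:
            fh.write(f">{name}\n")
            seq = contigs[name]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    from .genemodel_io import write_gtf

    write_gtf(models, gtf_path)
    # pyfaidx index from a previous run would go stale
    fai = fasta_path + ".fai"
    if os.path.exists(fai):
        os.remove(fai)
    return fasta_path, gtf_path


# ---------------------------------------------------------------------------
# Mutation catalogue
# ---------------------------------------------------------------------------

def _exon_spans(model: GeneModel) -> list[tuple[int, int]]:
    bounds = [0, *model.junction_offsets, model.cds_length]
    return list(zip(bounds, bounds[1:]))


def _pick_span(rng, spans, min_len: int) -> tuple[int, int] | None:
    ok = [s for s in spans if s[1] - s[0] >= min_len]
    if not ok:
        return None
    weights = np.array([b - a for a, b in ok], dtype=float)
    return ok[rng.choice(len(ok), p=weights / weights.sum())]


def _draw_mutation(
    model: GeneModel, mut_type: str, sample: str, rng: np.random.Generator
) -> CdsMutation | None:
    """One random mutation of the requested type, or None if impossible."""
    cds = model.cds_sequence
    L = model.cds_length
    spans = _exon_spans(model)
    klass = _CLASS_OF_TYPE[mut_type]

    if mut_type == "nonsense_snv":
        for _ in range(50):
            c = int(rng.integers(1, L // 3 - 1))
            codon = cds[3 * c : 3 * c + 3]
            cands = [(k, stop[k]) for stop in STOPS for k in range(3)
                     if sum(a != b for a, b in zip(codon, stop)) == 1
                     and codon[k] != stop[k]]
            if cands:
                k, alt = cands[int(rng.integers(len(cands)))]
                return CdsMutation(model.gene_id, sample, 3 * c + k,
                                   codon[k], alt, "snv", klass)
        return None
    if mut_type == "missense":
        for _ in range(50):
            c = int(rng.integers(1, L // 3 - 1))
            codon = cds[3 * c : 3 * c + 3]
            k = int(rng.integers(3))
            alt = rng.choice([b for b in BASES if b != codon[k]])
            new = codon[:k] + alt + codon[k + 1 :]
            if new in STOPS:
                continue
            if str(Seq(new).translate()) != str(Seq(codon).translate()):
                return CdsMutation(model.gene_id, sample, 3 * c + k,
                                   codon[k], str(alt), "snv", klass)
        return None
    if mut_type == "silent":
        for _ in range(50):
            c = int(rng.integers(1, L // 3 - 1))
            codon = cds[3 * c : 3 * c + 3]
            for alt in rng.permutation([b for b in BASES if b != codon[2]]):
                new = codon[:2] + alt
                if new not in STOPS and str(Seq(new).translate()) == str(
                    Seq(codon).translate()
                ):
                    return CdsMutation(model.gene_id, sample, 3 * c + 2,
                                       codon[2], str(alt), "snv", klass)
        return None
    if mut_type == "startloss":
        # break the initiator without creating a stop: ATG -> AAG
        return CdsMutation(model.gene_id, sample, 1, "T", "A", "snv", klass)
    if mut_type in ("frameshift_del", "inframe_del"):
        d = 3 if mut_type == "inframe_del" else int(rng.integers(1, 3))
        span = _pick_span(rng, spans, d + 2)
        if span is None:
            return None
        p = int(rng.integers(span[0], span[1] - d + 1))
        return CdsMutation(model.gene_id, sample, p, cds[p : p + d], "",
                           "del", klass)
    if mut_type == "frameshift_ins":
        n_ins = int(rng.integers(1, 3))
        span = _pick_span(rng, spans, 3)
        if span is None:
            return None
        p = int(rng.integers(span[0], span[1] - 1))  # p and p+1 share the span
        alt = "".join(rng.choice(list(BASES), size=n_ins))
        return CdsMutation(model.gene_id, sample, p, "", alt, "ins", klass)
    raise ValueError(f"unknown mutation type {mut_type!r}")


def random_cds_mutations(
    models: list[GeneModel], config: SimConfig
) -> list[tuple[CdsMutation, str]]:
    """Random CDS-level mutations with oracle truth labels, per the mix."""
    rng = config.rng(2)
    types = sorted(config.mutation_mix)
    probs = np.array([config.mutation_mix[t] for t in types])
    samples = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    out = []
    seen: set[tuple] = set()
    while len(out) < config.n_mutations:
        model = models[int(rng.integers(len(models)))]
        mut_type = types[int(rng.choice(len(types), p=probs))]
        sample = samples[int(rng.integers(len(samples)))]
        mut = _draw_mutation(model, mut_type, sample, rng)
        if mut is None:
            continue
        key = (mut.gene, mut.sample_id, mut.cds_pos, mut.ref, mut.alt)
        if key in seen:  # a chance re-draw would look like a duplicate record
            continue
        seen.add(key)
        truth = oracle_classify(model.cds_sequence,
                                list(model.junction_offsets), mut)
        out.append((mut, truth))
    return out


def simulate_mutations(
    models: list[GeneModel], config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MAF records plus a truth table of expected filter verdicts and classes.

    Includes the targeted boundary constructs (when their genes are among
    ``models``) and, unless disabled, deliberately planted filter cases:
    an excluded-class record, a reference mismatch, an exact duplicate, a
    junction-spanning deletion and an intronic record.
    """
    by_gene = {m.gene_id: m for m in models}
    maf_rows: list[dict] = []
    truth_rows: list[dict] = []

    def add(model: GeneModel, mut: CdsMutation, truth_class: str,
            verdict: str = "kept", name: str = "") -> None:
        start, end, ref, alt = lift_back(model, mut)
        maf_rows.append(dict(zip(MAF_COLUMNS, [
            mut.gene, model.chromosome, start, end, ref, alt,
            mut.source_class, mut.sample_id])))
        truth_rows.append({
            "maf_index": len(maf_rows) - 1, "gene": mut.gene,
            "sample_id": mut.sample_id, "source_class": mut.source_class,
            "mut_type": mut.mut_type, "cds_pos": mut.cds_pos,
            "ref": mut.ref, "alt": mut.alt,
            "expected_verdict": verdict, "expected_class": truth_class,
            "construct": name})

    for mut, truth in random_cds_mutations(models, config):
        add(by_gene[mut.gene], mut, truth)
    if config.include_boundary_genes:
        for case in boundary_constructs(config):
            if case.model.gene_id in by_gene:
                add(case.model, case.mutation, case.expected_class,
                    name=case.name)

    if config.plant_filter_cases and models:
        rng = config.rng(5)
        host = next((m for m in models if m.n_exons >= 2), models[0])
        # excluded variant class
        maf_rows.append(dict(zip(MAF_COLUMNS, [
            host.gene_id, host.chromosome, 1, 1, "A", "T", "3'UTR", "S0001"])))
        truth_rows.append({"maf_index": len(maf_rows) - 1,
                           "gene": host.gene_id, "sample_id": "S0001",
                           "source_class": "3'UTR", "mut_type": "snv",
                           "cds_pos": -1, "ref": "", "alt": "",
                           "expected_verdict": "class_excluded",
                           "expected_class": "", "construct": "filter_class"})
        # reference mismatch: report the wrong base at a real CDS position
        mis = _draw_mutation(host, "missense", "S0002", rng)
        start, end, ref, alt = lift_back(host, mis)
        wrong = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
        maf_rows.append(dict(zip(MAF_COLUMNS, [
            host.gene_id, host.chromosome, start, end, wrong, alt,
            "Missense_Mutation", "S0002"])))
        truth_rows.append({"maf_index": len(maf_rows) - 1,
                           "gene": host.gene_id, "sample_id": "S0002",
                           "source_class": "Missense_Mutation",
                           "mut_type": "snv", "cds_pos": mis.cds_pos,
                           "ref": "", "alt": "",
                           "expected_verdict": "ref_mismatch",
                           "expected_class": "", "construct": "filter_ref"})
        # exact duplicate of the first random record
        if maf_rows:
            dup = dict(maf_rows[0])
            maf_rows.append(dup)
            truth_rows.append({"maf_index": len(maf_rows) - 1,
                               "gene": dup["Hugo_Symbol"],
                               "sample_id": dup["Tumor_Sample_Barcode"],
                               "source_class": dup["Variant_Classification"],
                               "mut_type": "", "cds_pos": -1,
                               "ref": "", "alt": "",
                               "expected_verdict": "duplicate",
                               "expected_class": "",
                               "construct": "filter_duplicate"})
        if host.n_exons >= 2:
            # deletion spanning the first exon-intron boundary
            s0, e0 = host.cds_exons[0]
            maf_rows.append(dict(zip(MAF_COLUMNS, [
                host.gene_id, host.chromosome, e0 - 1, e0 + 2, "NNN", "-",
                "Frame_Shift_Del", "S0003"])))
            truth_rows.append({"maf_index": len(maf_rows) - 1,
                               "gene": host.gene_id, "sample_id": "S0003",
                               "source_class": "Frame_Shift_Del",
                               "mut_type": "del", "cds_pos": -1,
                               "ref": "", "alt": "",
                               "expected_verdict": "splice_excluded",
                               "expected_class": "",
                               "construct": "filter_splice"})
            # intronic SNV: outside every CDS exon
            maf_rows.append(dict(zip(MAF_COLUMNS, [
                host.gene_id, host.chromosome, e0 + 5, e0 + 5, "N", "A",
                "Missense_Mutation", "S0004"])))
            truth_rows.append({"maf_index": len(maf_rows) - 1,
                               "gene": host.gene_id, "sample_id": "S0004",
                               "source_class": "Missense_Mutation",
                               "mut_type": "snv", "cds_pos": -1,
                               "ref": "", "alt": "",
                               "expected_verdict": "outside_cds",
                               "expected_class": "",
                               "construct": "filter_outside"})

    return (pd.DataFrame(maf_rows, columns=MAF_COLUMNS),
            pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# Expression / CNV / annotations
# ---------------------------------------------------------------------------

def simulate_expression(
    models: list[GeneModel],
    truth: pd.DataFrame,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Log-scale expression, thresholded CNV and sample annotations.

    Wild-type expression of gene g in sample s is Normal(mu_g, sd) with
    mu_g ~ Normal(8, 2) and sd = ``background_noise_sd`` (log2 RSEM-like
    scale). Samples carrying an NMD-elicit mutation of a gene are shifted
    down by ``nmd_effect_size`` SD units; a fraction of those pairs may
    additionally receive a deletion call (CNV -1/-2) and a further
    ``codeletion_shift``.
    """
    rng = config.rng(3)
    genes = [m.gene_id for m in models]
    samples = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    mu = rng.normal(8.0, 2.0, size=len(genes))
    values = mu[:, None] + rng.normal(
        0.0, config.background_noise_sd, size=(len(genes), len(samples)))
    expr = pd.DataFrame(values, index=genes, columns=samples)
    cnv = pd.DataFrame(0, index=genes, columns=samples, dtype=int)

    kept = truth[(truth["expected_verdict"] == "kept")
                 & (truth["expected_class"] == "elicit")]
    shift = config.nmd_effect_size * config.background_noise_sd
    for gene, sample in {(r.gene, r.sample_id) for r in kept.itertuples()}:
        if gene not in expr.index or sample not in expr.columns:
            continue
        expr.loc[gene, sample] -= shift
        if config.codeletion_fraction and rng.random() < config.codeletion_fraction:
            cnv.loc[gene, sample] = int(rng.choice([-1, -2]))
            expr.loc[gene, sample] -= config.codeletion_shift

    ann = pd.DataFrame({"cancer": ["SYNCAN"] * len(samples),
                        "msi": ["MSS"] * len(samples)}, index=samples)
    ann.index.name = "sample_id"
    return expr, cnv, ann


# ---------------------------------------------------------------------------
# Hypermutation cohort for enrichment recovery
# ---------------------------------------------------------------------------

def simulate_enrichment_cohort(
    seed: int,
    n_null_genes: int = 200,
    n_planted: int = 5,
    fold: float = 5.0,
    n_hyper: int = 10,
    n_nonhyper: int = 320,
    mean_elicit: float = 24.0,
    mean_silent: float = 48.0,
) -> tuple[pd.DataFrame, dict[str, int], list[str]]:
    """Mutation events for a cohort with planted hypermutation-permissive genes.

    Null genes draw Poisson counts of elicit and silent mutations with the
    same elicit:silent ratio in both strata; planted genes have their
    elicit rate multiplied by ``fold`` in the hypermutated stratum only.
    Per-stratum sample totals are sized so hypermutated samples exceed
    1,000 events and non-hypermutated ones stay below 100.

    Returns (event table, per-sample counts, planted gene names).
    """
    rng = np.random.default_rng([seed, 4])
    hyper_samples = [f"H{i + 1:03d}" for i in range(n_hyper)]
    nonhyper_samples = [f"N{i + 1:03d}" for i in range(n_nonhyper)]
    genes = [f"NULL{i + 1:04d}" for i in range(n_null_genes)]
    planted = [f"PLANT{i + 1:02d}" for i in range(n_planted)]
    rows = []
    for gene in genes + planted:
        for stratum, samples in (("hyper", hyper_samples),
                                 ("non_hyper", nonhyper_samples)):
            lam_e = mean_elicit * (fold if (gene in planted
                                            and stratum == "hyper") else 1.0)
            for klass, nmd, lam in (("Nonsense_Mutation", "elicit", lam_e),
                                    ("Silent", "", mean_silent)):
                n = int(rng.poisson(lam))
                for s in rng.choice(samples, size=n):
                    rows.append({"gene": gene, "sample_id": str(s),
                                 "source_class": klass, "nmd_class": nmd})
    events = pd.DataFrame(rows)
    counts = events.groupby("sample_id").size().to_dict()
    for s in hyper_samples + nonhyper_samples:
        counts.setdefault(s, 0)
    return events, counts, planted


def write_fixture_set(config: SimConfig, outdir: str) -> dict[str, str]:
    """Run every generator and write the full fixture set to ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    fasta, gtf = simulate_genome(config, outdir)
    models, _ = generate_genes(config)
    maf, truth = simulate_mutations(models, config)
    expr, cnv, ann = simulate_expression(models, truth, config)
    paths = {"fasta": fasta, "gtf": gtf,
             "maf": os.path.join(outdir, "mutations.maf"),
             "truth": os.path.join(outdir, "truth.tsv"),
             "expr": os.path.join(outdir, "expr.tsv"),
             "cnv": os.path.join(outdir, "cnv.tsv"),
             "samples": os.path.join(outdir, "samples.tsv")}
    maf.to_csv(paths["maf"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    expr.to_csv(paths["expr"], sep="\t", index_label="gene")
    cnv.to_csv(paths["cnv"], sep="\t", index_label="gene")
    ann.to_csv(paths["samples"], sep="\t")
    return paths
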