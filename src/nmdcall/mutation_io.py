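"""MAF parsing, mutation-level exclusion filters, and genomic→CDS lifting.

The MAF dialect accepted is the TCGA one: tab-separated with at least the
gene symbol, chromosome, 1-based inclusive start/end, reference and tumour
alleles, variant classification and sample barcode. Alleles are reported on
the forward genomic strand; for genes on '-' they are reverse-complemented
during the lift. "-" denotes the empty allele (pure insertion/deletion).

Exclusion filters mirror the study pre-filters: splice/UTR/intergenic
classes are dropped, reference-mismatching records are dropped, exact
duplicate annotations are collapsed (distinct mutations in the same gene and
sample are all retained), and any mutation whose genomic footprint is not
fully inside a single CDS exon is excluded as splice-proximal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .genemodel_io import GeneModel, exon_index_of, genomic_to_cds, cds_to_genomic, revcomp

#: TCGA variant classes excluded from NMD analysis.
EXCLUDED_CLASSES = frozenset(
    {"Splice_Site", "3'UTR", "5'UTR", "IGR", "Intron", "RNA"}
)

_COLUMN_ALIASES = {
    "gene": ("hugo_symbol", "gene", "gene_symbol"),
    "chromosome": ("chromosome", "chrom", "chr"),
    "start": ("start_position", "start", "start_pos"),
    "end": ("end_position", "end", "end_pos"),
    "ref_allele": ("reference_allele", "ref_allele", "ref"),
    "alt_allele": ("tumor_seq_allele2", "alt_allele", "tumour_seq_allele2", "alt"),
    "variant_class": ("variant_classification", "variant_class"),
    "sample_id": ("tumor_sample_barcode", "sample_id", "sample", "tumour_sample_barcode"),
}


@dataclass(frozen=True)
class MafRecord:
    gene: str
    chromosome: str
    start: int  # 1-based
    end: int  # 1-based inclusive
    ref_allele: str  # "-" for pure insertion
    alt_allele: str  # "-" for pure deletion
    variant_class: str
    sample_id: str


@dataclass(frozen=True)
class CdsMutation:
    """A mutation lifted onto the spliced CDS (translation orientation).

    ``cds_pos`` is the 0-based offset of the first affected base for
    snv/del/delins; for insertions it is the offset of the base *after
    which* the new bases are inserted. ``ref``/``alt`` are in translation
    orientation and empty for pure ins/del respectively.
    """

    gene: str
    sample_id: str
    cds_pos: int
    ref: str
    alt: str
    mut_type: str  # snv | ins | del | delins
    source_class: str


@dataclass(frozen=True)
class FilterReport:
    record_index: int
    verdict: str  # kept | splice_excluded | class_excluded | ref_mismatch
    #            # | duplicate | outside_cds | gene_unknown
    detail: str = ""


def _normalise_class(value: str) -> str:
    # tolerate typographic primes in UTR class names
    return str(value).replace("′", "'").strip()


def _normalise_chrom(value: str) -> str:
    v = str(value).strip()
    return v[3:] if v.lower().startswith("chr") else v


def read_maf(path: str) -> list[MafRecord]:
    """Read a TCGA-style MAF into records, in file order."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    lower = {c.lower(): c for c in df.columns}
    resolved = {}
    for field, aliases in _COLUMN_ALIASES.items():
        col = next((lower[a] for a in aliases if a in lower), None)
        if col is None:
            raise ValueError(f"MAF {path} is missing a required column for {field!r} "
                             f"(accepted names: {', '.join(aliases)})")
        resolved[field] = col
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        records.append(
            MafRecord(
                gene=d[resolved["gene"]],
                chromosome=_normalise_chrom(d[resolved["chromosome"]]),
                start=int(d[resolved["start"]]),
                end=int(d[resolved["end"]]),
                ref_allele=d[resolved["ref_allele"]].strip().upper() or "-",
                alt_allele=d[resolved["alt_allele"]].strip().upper() or "-",
                variant_class=_normalise_class(d[resolved["variant_class"]]),
                sample_id=d[resolved["sample_id"]],
            )
        )
    return records


def _mut_type(ref: str, alt: str) -> str:
    if not ref:
        return "ins"
    if not alt:
        return "del"
    if len(ref) == 1 and len(alt) == 1:
        return "snv"
    return "delins"


def filter_and_map(
    records: Iterable[MafRecord], models: Mapping[str, GeneModel]
) -> tuple[list[CdsMutation], list[FilterReport]]:
    """Apply exclusion filters and lift surviving mutations to CDS coordinates.

    Every input record gets exactly one FilterReport. Checks run in order:
    excluded variant class → unknown gene → exact duplicate → CDS footprint
    (outside_cds when no overlap, splice_excluded when partially outside a
    single exon) → reference-allele match against the extracted CDS.
    """
    kept: list[CdsMutation] = []
    reports: list[FilterReport] = []
    seen: set[tuple] = set()

    for idx, rec in enumerate(records):
        if _normalise_class(rec.variant_class) in EXCLUDED_CLASSES:
            reports.append(FilterReport(idx, "class_excluded", rec.variant_class))
            continue
        model = models.get(rec.gene)
        if model is None:
            reports.append(FilterReport(idx, "gene_unknown", rec.gene))
            continue
        key = (rec.gene, rec.sample_id, rec.chromosome, rec.start, rec.end,
               rec.ref_allele, rec.alt_allele)
        if key in seen:
            reports.append(FilterReport(idx, "duplicate"))
            continue
        seen.add(key)
        if _normalise_chrom(model.chromosome) != _normalise_chrom(rec.chromosome):
            reports.append(FilterReport(
                idx, "outside_cds",
                f"record on {rec.chromosome}, gene on {model.chromosome}"))
            continue

        ref = "" if rec.ref_allele == "-" else rec.ref_allele
        alt = "" if rec.alt_allele == "-" else rec.alt_allele
        mut_type = _mut_type(ref, alt)

        if mut_type == "ins":
            # start/end flank the insertion; both flanks must share one exon
            left, right = rec.start - 1, rec.end - 1
            ei_l, ei_r = exon_index_of(model, left), exon_index_of(model, right)
            if ei_l is None and ei_r is None:
                reports.append(FilterReport(idx, "outside_cds"))
                continue
            if ei_l is None or ei_r is None or ei_l != ei_r:
                reports.append(FilterReport(idx, "splice_excluded",
                                            "insertion at exon boundary"))
                continue
            anchor = left if model.strand == "+" else right
            cds_pos = genomic_to_cds(model, anchor)
            cds_alt = alt if model.strand == "+" else revcomp(alt)
            kept.append(CdsMutation(rec.gene, rec.sample_id, cds_pos, "", cds_alt,
                                    "ins", rec.variant_class))
            reports.append(FilterReport(idx, "kept"))
            continue

        # snv / del / delins: footprint is [start-1, end) 0-based
        g0, g1 = rec.start - 1, rec.end  # half-open
        idxs = {exon_index_of(model, g) for g in range(g0, g1)}
        if idxs == {None}:
            reports.append(FilterReport(idx, "outside_cds"))
            continue
        if None in idxs or len(idxs) != 1:
            reports.append(FilterReport(idx, "splice_excluded",
                                        "footprint crosses an exon boundary"))
            continue
        anchor = g0 if model.strand == "+" else g1 - 1
        cds_pos = genomic_to_cds(model, anchor)
        cds_ref = ref if model.strand == "+" else revcomp(ref)
        cds_alt = alt if model.strand == "+" else revcomp(alt)
        if model.cds_sequence[cds_pos : cds_pos + len(cds_ref)] != cds_ref:
            reports.append(FilterReport(
                idx, "ref_mismatch",
                f"MAF ref {rec.ref_allele} vs CDS "
                f"{model.cds_sequence[cds_pos:cds_pos + len(cds_ref)]}"))
            continue
        kept.append(CdsMutation(rec.gene, rec.sample_id, cds_pos, cds_ref, cds_alt,
                                mut_type, rec.variant_class))
        reports.append(FilterReport(idx, "kept"))
    return kept, reports


def lift_back(model: GeneModel, mut: CdsMutation) -> tuple[int, int, str, str]:
    """Map a CdsMutation back to MAF genomic coordinates.

    Returns (start, end, ref, alt) with 1-based inclusive coordinates and
    forward-strand alleles ("-" for empty), i.e. the MAF representation.
    """
    if mut.mut_type == "ins":
        anchor = cds_to_genomic(model, mut.cds_pos)
        if model.strand == "+":
            start, end = anchor + 1, anchor + 2
            ref, alt = "-", mut.alt
        else:
            start, end = anchor, anchor + 1
            ref, alt = "-", revcomp(mut.alt)
        return start, end, ref, alt
    first = cds_to_genomic(model, mut.cds_pos)
    last = cds_to_genomic(model, mut.cds_pos + len(mut.ref) - 1)
    g0, g1 = min(first, last), max(first, last)
    if model.strand == "+":
        ref, alt = mut.ref, mut.alt
    else:
        ref, alt = revcomp(mut.ref), revcomp(mut.alt)
    return g0 + 1, g1 + 1, ref or "-", alt or "-"


def write_filter_report(reports: Iterable[FilterReport], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("record_index\tverdict\tdetail\n")
        for r in reports:
            fh.write(f"{r.record_index}\t{r.verdict}\t{r.detail}\n")
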