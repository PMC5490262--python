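"""Gene models: canonical CDS extraction with exon-junction offsets.

A gene model here is deliberately minimal: the ordered coding-exon intervals
of one transcript, the spliced CDS in translation orientation, and the
positions of the exon-exon junctions *within the CDS*. UTR exon structure is
not modelled; the junctions that matter for NMD prediction are the ones the
ribosome can encounter while translating the coding sequence.

Coordinates are normalised to 0-based half-open internally. GTF input is
read as 1-based inclusive, BED12 as 0-based half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import gffutils
import pyfaidx
from Bio.Seq import Seq

START_CODON = "ATG"
STOP_CODONS = frozenset({"TGA", "TAA", "TAG"})


def revcomp(seq: str) -> str:
    """Reverse complement (delegates to Bio.Seq)."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GeneModel:
    """One gene's canonical transcript reduced to its spliced CDS.

    Attributes
    ----------
    cds_exons
        Genomic CDS intervals, 0-based half-open, ascending genomic order
        (regardless of strand).
    cds_sequence
        Spliced CDS in translation orientation; for strand '-' this is the
        reverse complement of the concatenated genomic intervals.
    junction_offsets
        For each internal exon-exon junction, the number of spliced-CDS
        nucleotides strictly upstream of it, in translation orientation.
        ``n_exons - 1`` entries, strictly ascending.
    """

    gene_id: str
    transcript_id: str
    chromosome: str
    strand: str
    cds_exons: tuple[tuple[int, int], ...]
    cds_sequence: str
    junction_offsets: tuple[int, ...]

    @property
    def n_exons(self) -> int:
        return len(self.cds_exons)

    @property
    def cds_length(self) -> int:
        return len(self.cds_sequence)

    def __post_init__(self) -> None:
        total = sum(e - s for s, e in self.cds_exons)
        if total != len(self.cds_sequence):
            raise ValueError(
                f"{self.gene_id}: CDS length {len(self.cds_sequence)} != "
                f"sum of exon lengths {total}"
            )
        if len(self.junction_offsets) != self.n_exons - 1:
            raise ValueError(f"{self.gene_id}: junction/exon count mismatch")
        for j in self.junction_offsets:
            if not 0 < j < total:
                raise ValueError(f"{self.gene_id}: junction offset {j} out of range")


@dataclass(frozen=True)
class QcReport:
    """Wild-type quality verdict for one gene."""

    gene_id: str
    transcript_id: str
    verdict: str  # pass | wt_ptc | no_start | no_stop | duplicate_id
    detail: str = ""


def build_gene_model(
    gene_id: str,
    transcript_id: str,
    chromosome: str,
    strand: str,
    cds_exons: Sequence[tuple[int, int]],
    genome: Mapping[str, object],
) -> GeneModel:
    """Assemble a GeneModel from genomic intervals and a sequence source.

    ``genome`` maps contig name to anything sliceable yielding sequence
    (a :class:`pyfaidx.Fasta`, or a plain dict of strings for tests).
    """
    if strand not in "+-":
        raise ValueError(f"{transcript_id}: bad strand {strand!r}")
    exons = sorted((int(s), int(e)) for s, e in cds_exons)
    for s, e in exons:
        if e <= s:
            raise ValueError(f"{transcript_id}: empty/inverted interval [{s},{e})")
    if chromosome not in genome:
        raise ValueError(
            f"{transcript_id}: chromosome {chromosome!r} not present in FASTA"
        )
    contig = genome[chromosome]
    chunks = [str(contig[s:e]).upper() for s, e in exons]
    plus = "".join(chunks)
    if strand == "+":
        seq = plus
        lengths = [e - s for s, e in exons]
    else:
        seq = revcomp(plus)
        lengths = [e - s for s, e in reversed(exons)]
    offsets, acc = [], 0
    for ln in lengths[:-1]:
        acc += ln
        offsets.append(acc)
    return GeneModel(
        gene_id=gene_id,
        transcript_id=transcript_id,
        chromosome=chromosome,
        strand=strand,
        cds_exons=tuple(exons),
        cds_sequence=seq,
        junction_offsets=tuple(offsets),
    )


# ---------------------------------------------------------------------------
# Coordinate maps between genome and spliced CDS (translation orientation)
# ---------------------------------------------------------------------------

def genomic_to_cds(model: GeneModel, gpos: int) -> int | None:
    """Map a 0-based genomic position to its spliced-CDS offset, or None."""
    acc = 0
    plus_off = None
    for s, e in model.cds_exons:
        if s <= gpos < e:
            plus_off = acc + (gpos - s)
            break
        acc += e - s
    if plus_off is None:
        return None
    if model.strand == "+":
        return plus_off
    return model.cds_length - 1 - plus_off


def cds_to_genomic(model: GeneModel, offset: int) -> int:
    """Inverse of :func:`genomic_to_cds`; returns a 0-based genomic position."""
    if not 0 <= offset < model.cds_length:
        raise ValueError(f"CDS offset {offset} out of range")
    plus_off = offset if model.strand == "+" else model.cds_length - 1 - offset
    acc = 0
    for s, e in model.cds_exons:
        if plus_off < acc + (e - s):
            return s + (plus_off - acc)
        acc += e - s
    raise AssertionError("unreachable")


def exon_index_of(model: GeneModel, gpos: int) -> int | None:
    """Index (genomic order) of the CDS exon containing a genomic position."""
    for i, (s, e) in enumerate(model.cds_exons):
        if s <= gpos < e:
            return i
    return None


# ---------------------------------------------------------------------------
# Wild-type QC
# ---------------------------------------------------------------------------

def qc_filter(model: GeneModel) -> QcReport:
    """Apply the wild-type pre-filters.

    wt_ptc: an in-frame stop ends before the final codon (such transcripts
    would be NMD substrates without any mutation, or are misannotated);
    no_start: CDS does not begin with ATG; no_stop: the final in-frame codon
    is not a stop (including CDS length not a multiple of 3).
    """
    seq = model.cds_sequence
    n = len(seq)
    for i in range(0, n - n % 3 - 3, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return QcReport(
                model.gene_id, model.transcript_id, "wt_ptc",
                f"in-frame stop at CDS offset {i}",
            )
    if not seq.startswith(START_CODON):
        return QcReport(
            model.gene_id, model.transcript_id, "no_start",
            f"CDS begins with {seq[:3]}",
        )
    if n % 3 != 0 or seq[n - 3 :] not in STOP_CODONS:
        return QcReport(
            model.gene_id, model.transcript_id, "no_stop",
            "final in-frame codon is not a stop",
        )
    return QcReport(model.gene_id, model.transcript_id, "pass")


def select_canonical(models: Sequence[GeneModel]) -> GeneModel:
    """Canonical isoform: the longest CDS; ties break on smallest transcript_id."""
    if not models:
        raise ValueError("empty model list")
    gene_ids = {m.gene_id for m in models}
    if len(gene_ids) != 1:
        raise ValueError(f"mixed gene_ids {sorted(gene_ids)}")
    return min(models, key=lambda m: (-m.cds_length, m.transcript_id))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_gtf_transcripts(path: str):
    """Yield (gene_id, transcript_id, chrom, strand, [(start0, end0), ...])."""
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # pragma: no cover - passthrough with context
        raise ValueError(f"malformed GTF {path}: {exc}") from exc
    groups: dict[tuple[str, str], dict] = {}
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        gene = feat.attributes.get("gene_id", [feat.id])[0]
        tx = feat.attributes.get("transcript_id", [feat.id])[0]
        rec = groups.setdefault(
            (gene, tx), {"chrom": feat.seqid, "strand": feat.strand, "exons": []}
        )
        # GTF is 1-based inclusive
        rec["exons"].append((feat.start - 1, feat.end))
    for (gene, tx), rec in groups.items():
        yield gene, tx, rec["chrom"], rec["strand"], rec["exons"]


def _read_bed12_transcripts(path: str):
    """BED12: blocks are taken as the CDS exons; name is 'gene|transcript'."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path} line {lineno}: expected 12 BED columns")
            try:
                chrom, start = parts[0], int(parts[1])
                name, strand = parts[3], parts[5]
                n_blocks = int(parts[9])
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                starts = [int(x) for x in parts[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path} line {lineno}: block count mismatch")
            gene, _, tx = name.partition("|")
            exons = [(start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)]
            yield gene, tx or name, chrom, strand, exons


def load_gene_models(
    annotation_path: str, fasta_path: str
) -> tuple[list[GeneModel], list[QcReport]]:
    """Load gene models, select canonical isoforms and run wild-type QC.

    Returns the canonical models that pass QC plus one QcReport per gene
    (pass / wt_ptc / no_start / no_stop / duplicate_id). Genes whose id maps
    to transcripts on more than one chromosome or strand are rejected as
    duplicate_id (the analogue of ambiguous gene-identifier mapping).
    """
    genome = pyfaidx.Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    ext = os.path.splitext(str(annotation_path))[1].lower()
    reader = _read_bed12_transcripts if ext == ".bed" else _read_gtf_transcripts

    per_gene: dict[str, list[GeneModel]] = {}
    loci: dict[str, set[tuple[str, str]]] = {}
    for gene, tx, chrom, strand, exons in reader(str(annotation_path)):
        model = build_gene_model(gene, tx, chrom, strand, exons, genome)
        per_gene.setdefault(gene, []).append(model)
        loci.setdefault(gene, set()).add((chrom, strand))

    models: list[GeneModel] = []
    reports: list[QcReport] = []
    for gene in sorted(per_gene):
        if len(loci[gene]) > 1:
            reports.append(
                QcReport(gene, "", "duplicate_id",
                         f"maps to {len(loci[gene])} distinct loci")
            )
            continue
        canon = select_canonical(per_gene[gene])
        report = qc_filter(canon)
        reports.append(report)
        if report.verdict == "pass":
            models.append(canon)
    return models, reports


def write_gtf(models: Iterable[GeneModel], path: str) -> None:
    """Write CDS features (1-based inclusive) with gene_id/transcript_id."""
    with open(path, "w") as fh:
        for m in models:
            for s, e in m.cds_exons:
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
                fh.write(
                    "\t".join(
                        [m.chromosome, "nmdcall", "CDS", str(s + 1), str(e),
                         ".", m.strand, "0", attrs]
                    )
                    + "\n"
                )


def write_qc_report(reports: Iterable[QcReport], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttranscript_id\tverdict\tdetail\n")
        for r in reports:
            fh.write(f"{r.gene_id}\t{r.transcript_id}\t{r.verdict}\t{r.detail}\n")
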