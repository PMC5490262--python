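"""Shared fixtures: toy genes built by hand and seeded synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

from nmdcall import SimConfig, build_gene_model
from nmdcall.synthetic_data import generate_genes


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def toy_genome():
    """One synthetic contig with deterministic random sequence."""
    rng = np.random.default_rng(42)
    return {"chrT": _rand_seq(rng, 1000)}


@pytest.fixture
def two_exon_plus(toy_genome):
    """Two CDS exons [100,250)+[400,550) on '+': 300 nt, junction at 150."""
    return build_gene_model("TOY1", "TOY1.t1", "chrT", "+",
                            [(100, 250), (400, 550)], toy_genome)


@pytest.fixture
def two_exon_minus(toy_genome):
    return build_gene_model("TOY1", "TOY1.t1", "chrT", "-",
                            [(100, 250), (400, 550)], toy_genome)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=1, n_genes=8, n_samples=40, n_mutations=120)


@pytest.fixture(scope="session")
def sim_models(sim_config):
    models, contigs = generate_genes(sim_config)
    return models, contigs


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, sim_config):
    """A complete written fixture set (FASTA/GTF/MAF/expr/...)."""
    from nmdcall import write_fixture_set

    outdir = tmp_path_factory.mktemp("fixtures")
    paths = write_fixture_set(sim_config, str(outdir))
    return paths


def make_model_from_cds(gene_id, cds, junction_offsets, strand="+",
                        n_flank=25, seed=0):
    """Place a given spliced CDS on a fresh contig and return the model.

    Independent of the synthetic_data assembly path: intervals are laid out
    here by direct arithmetic, introns of fixed length 40.
    """
    from nmdcall.genemodel_io import revcomp

    rng = np.random.default_rng(seed)
    bounds = [0, *junction_offsets, len(cds)]
    chunks = [cds[a:b] for a, b in zip(bounds, bounds[1:])]
    if strand == "-":
        genomic_chunks = [revcomp(c) for c in reversed(chunks)]
    else:
        genomic_chunks = chunks
    pos = n_flank
    pieces = [_rand_seq(rng, n_flank)]
    intervals = []
    for i, ch in enumerate(genomic_chunks):
        intervals.append((pos, pos + len(ch)))
        pieces.append(ch)
        pos += len(ch)
        if i < len(genomic_chunks) - 1:
            pieces.append(_rand_seq(rng, 40))
            pos += 40
    pieces.append(_rand_seq(rng, n_flank))
    contig = f"ctg_{gene_id}"
    genome = {contig: "".join(pieces)}
    model = build_gene_model(gene_id, gene_id + ".t1", contig, strand,
                             intervals, genome)
    assert model.cds_sequence == cds
    return model, genome
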