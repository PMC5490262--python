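"""The classifier: sequence editing, ORF relocation, rules, oracle parity."""

import numpy as np
import pytest

from nmdcall import (
    NmdConfig,
    apply_mutation,
    classify,
    classify_batch,
    evaluate_rules,
    find_orf,
)
from nmdcall.mutation_io import CdsMutation
from nmdcall.synthetic_data import (
    SimConfig,
    boundary_constructs,
    generate_genes,
    oracle_classify,
    random_cds_mutations,
)
from conftest import make_model_from_cds


def _clean_cds(n_codons, planted=None, seed=3):
    rng = np.random.default_rng(seed)
    from nmdcall.synthetic_data import NON_STOP_CODONS

    codons = ["ATG"] + list(rng.choice(NON_STOP_CODONS, size=n_codons - 2)) \
        + ["TAA"]
    for i, c in (planted or {}).items():
        codons[i] = c
    return "".join(codons)


def _snv(gene, pos, ref, alt, klass="Nonsense_Mutation"):
    return CdsMutation(gene, "S1", pos, ref, alt, "snv", klass)


# ---------------------------------------------------------------------------
# apply_mutation
# ---------------------------------------------------------------------------

def test_apply_mutation_junction_shifts():
    cds = _clean_cds(100)  # 300 nt
    model, _ = make_model_from_cds("G", cds, [150])
    snv = _snv("G", 10, cds[10], "A" if cds[10] != "A" else "C")
    assert apply_mutation(model, snv).junction_offsets == (150,)

    del1 = CdsMutation("G", "S1", 10, cds[10], "", "del", "Frame_Shift_Del")
    ms = apply_mutation(model, del1)
    assert len(ms.sequence) == 299 and ms.junction_offsets == (149,)

    ins2 = CdsMutation("G", "S1", 200, "", "GG", "ins", "Frame_Shift_Ins")
    ms = apply_mutation(model, ins2)
    assert len(ms.sequence) == 302 and ms.junction_offsets == (150,)


def test_apply_mutation_rejects_ref_mismatch():
    cds = _clean_cds(100)
    model, _ = make_model_from_cds("G", cds, [150])
    wrong = "A" if cds[10] != "A" else "C"
    with pytest.raises(ValueError, match="does not match"):
        apply_mutation(model, _snv("G", 10, wrong, "G"))


# ---------------------------------------------------------------------------
# find_orf
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "seq,expected",
    [("ATGAAATAA", (0, 6, True)),
     ("CCATGTAA", (2, 5, True)),
     ("ATGAAAAA", (0, None, False)),
     ("CCCCCCCC", (None, None, False))],
)
def test_find_orf(seq, expected):
    assert find_orf(seq) == expected


def test_find_orf_honours_alternative_start_codons():
    assert find_orf("CCATACCCTAA", start_codons=("ATG", "ATA")) == (2, 8, True)
    assert find_orf("CCATACCCTAA") == (None, None, False)


# ---------------------------------------------------------------------------
# classify: the worked examples
# ---------------------------------------------------------------------------

def test_nonsense_snv_deep_in_two_exon_gene_elicits():
    """PTC at offset 249 of a 402-nt CDS, junction at 350: all rules hold."""
    cds = _clean_cds(134, planted={83: "TAC"})  # offset 249..251
    model, _ = make_model_from_cds("G", cds, [350])
    call = classify(model, _snv("G", 251, "C", "A"))  # TAC -> TAA
    assert call.nmd_class == "elicit"
    assert (call.d_start, call.d_junction) == (249, 350 - 252)
    assert oracle_classify(cds, [350], _snv("G", 251, "C", "A")) == "elicit"


def test_single_exon_nonsense_escapes():
    cds = _clean_cds(134, planted={83: "TAC"})
    model, _ = make_model_from_cds("G", cds, [])
    call = classify(model, _snv("G", 251, "C", "A"))
    assert call.nmd_class == "escape"
    assert not call.rule_multi_exon and not call.rule_junction
    assert call.rule_startdist


def test_silent_change_in_final_stop_codon_is_non_ptc():
    cds = _clean_cds(134)  # ends TAA
    model, _ = make_model_from_cds("G", cds, [350])
    # TAA -> TAG: still a stop, still terminal
    call = classify(model, _snv("G", len(cds) - 1, "A", "G", "Silent"))
    assert call.nmd_class == "non_ptc"
    assert call.ptc_start is None


def test_frameshift_deletion_matches_oracle():
    cds = _clean_cds(200)
    model, _ = make_model_from_cds("G", cds, [450])
    mut = CdsMutation("G", "S1", 30, cds[30], "", "del", "Frame_Shift_Del")
    call = classify(model, mut)
    assert call.nmd_class == oracle_classify(cds, [450], mut)
    assert call.nmd_class in {"elicit", "escape", "non_ptc"}


def test_wild_type_neutral_edit_is_non_ptc():
    cds = _clean_cds(134)
    model, _ = make_model_from_cds("G", cds, [350])
    call = classify(model, _snv("G", 30, cds[30], cds[30], "Silent"))
    assert call.nmd_class == "non_ptc"


def test_start_loss_flags_relocated_start():
    cds = _clean_cds(151)
    model, _ = make_model_from_cds("G", cds, [300])
    call = classify(model, _snv("G", 1, "T", "A", "Translation_Start_Site"))
    if call.start_offset is not None and call.start_offset > 0:
        assert "start_relocated" in call.flags
    assert call.nmd_class == oracle_classify(
        cds, [300], _snv("G", 1, "T", "A", "Translation_Start_Site"))


def test_nonstop_variant_flagged():
    cds = _clean_cds(151)
    model, _ = make_model_from_cds("G", cds, [300])
    call = classify(model, _snv("G", len(cds) - 3, "T", "A",
                                "Nonstop_Mutation"))
    assert call.nmd_class == "non_ptc"
    assert "nonstop" in call.flags


# ---------------------------------------------------------------------------
# Rule thresholds are strict inequalities
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "d_start,d_junction,expect_junc,expect_start",
    [(201, 50, False, True), (201, 51, True, True),
     (200, 99, True, False), (201, 99, True, True),
     (175, 99, True, False)],
)
def test_rule_thresholds_are_strict(d_start, d_junction, expect_junc,
                                    expect_start):
    r_exon, r_junc, r_start = evaluate_rules(2, d_start, d_junction)
    assert r_exon
    assert r_junc is expect_junc
    assert r_start is expect_start


def test_boundary_constructs_classify_exactly(sim_config):
    """The mandated boundary fixtures yield exactly the forced classes."""
    for case in boundary_constructs(sim_config):
        call = classify(case.model, case.mutation)
        assert call.nmd_class == case.expected_class, case.name
        if case.expected_d_start is not None:
            assert call.d_start == case.expected_d_start, case.name
        if case.expected_d_junction is not None:
            assert call.d_junction == case.expected_d_junction, case.name


def test_moving_junction_downstream_never_unmakes_elicit():
    """With the PTC fixed, a more downstream last junction keeps eliciting."""
    cds = _clean_cds(200, planted={100: "TAC"})
    mut = _snv("G", 302, "C", "A")
    was_elicit = False
    for junction in range(304, 597, 25):
        model, _ = make_model_from_cds("G", cds, [junction])
        call = classify(model, mut)
        if was_elicit:
            assert call.nmd_class == "elicit"
        was_elicit = was_elicit or call.nmd_class == "elicit"
    assert was_elicit


# ---------------------------------------------------------------------------
# Batch behaviour
# ---------------------------------------------------------------------------

def test_classify_batch_counts_and_crosstab(sim_config):
    cases = boundary_constructs(sim_config)
    models = {c.model.gene_id: c.model for c in cases}
    table, crosstab = classify_batch(models, [c.mutation for c in cases])
    expected = {c.expected_class for c in cases}
    assert set(table["nmd_class"]) == expected
    assert len(table) == len(cases)
    assert crosstab.to_numpy().sum() == len(cases)
    # the in-frame deletion is NMD-elicit despite its in-frame source class
    row = table[table["source_class"] == "In_Frame_Del"].iloc[0]
    assert row["nmd_class"] == "elicit"


def test_classify_batch_empty():
    table, crosstab = classify_batch({}, [])
    assert table.empty and crosstab.empty


def test_combined_sample_mutations_mode():
    """Two frameshifts in one sample can restore the frame when combined."""
    cds = _clean_cds(200)
    model, _ = make_model_from_cds("G", cds, [450])
    d1 = CdsMutation("G", "S1", 30, cds[30], "", "del", "Frame_Shift_Del")
    d2 = CdsMutation("G", "S1", 60, cds[60], "", "del", "Frame_Shift_Del")
    d3 = CdsMutation("G", "S1", 90, cds[90], "", "del", "Frame_Shift_Del")
    combined = classify_batch(
        {"G": model}, [d1, d2, d3],
        NmdConfig(combine_sample_mutations=True))[0]
    assert len(combined) == 1  # one call per gene+sample
    independent = classify_batch({"G": model}, [d1, d2, d3])[0]
    assert len(independent) == 3


# ---------------------------------------------------------------------------
# Oracle equivalence (a fuller run lives in the acceptance suite)
# ---------------------------------------------------------------------------

def test_classifier_agrees_with_oracle_on_random_mutations():
    config = SimConfig(seed=17, n_genes=12, n_mutations=300)
    models, _ = generate_genes(config)
    by_gene = {m.gene_id: m for m in models}
    for mut, truth in random_cds_mutations(models, config):
        assert classify(by_gene[mut.gene], mut).nmd_class == truth
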