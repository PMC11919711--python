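"""Library-design operations: DR assignments, filters, assembly, designs."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from casarray import (
    DR_ASSIGNMENTS,
    DR_SEQUENCES,
    FilterConfig,
    FlankConfig,
    GenomicInterval,
    Spacer,
    assemble_array,
    assign_direct_repeats,
    derive_nontargeting_spacers,
    design_sublibrary_A,
    design_sublibrary_B,
    design_tiling_library,
    emit_cloning_oligos,
    filter_spacers,
    group_testing_coverage,
    random_spacers,
    revcomp,
    sample_negative_control_constructs,
    select_intergenic_control_regions,
)

# ------------------------------------------------------------ direct repeats


def test_all_direct_repeats_are_19nt():
    assert all(len(seq) == 19 for seq in DR_SEQUENCES.values())


@pytest.mark.parametrize(
    "plex,expected",
    [
        (1, ("WT", "DR8")),
        (3, ("WT", "DR1", "DR3", "DR8")),
        (6, ("WT", "DR1", "DR16", "DR18", "DR10", "DR3", "DR8")),
        (
            10,
            (
                "WT",
                "DR1",
                "DR16",
                "DR_NS1",
                "DR4",
                "DR_NS2",
                "DR17",
                "DR18",
                "DR10",
                "DR3",
                "DR8",
            ),
        ),
    ],
)
def test_assign_direct_repeats_matches_reference_tables(plex, expected):
    assignment = assign_direct_repeats(plex)
    assert assignment.names == expected
    assert len(assignment.ordered_drs) == plex + 1


def test_every_assignment_starts_wt_ends_dr8():
    for plex in DR_ASSIGNMENTS:
        names = assign_direct_repeats(plex).names
        assert names[0] == "WT" and names[-1] == "DR8"
        assert len(set(names)) == len(names)


def test_unsupported_plex_is_an_error():
    with pytest.raises(ValueError, match="supported"):
        assign_direct_repeats(2)


def test_custom_assignment_accepted_for_unsupported_plex():
    a = assign_direct_repeats(2, custom=["WT", "DR1", "DR8"])
    assert a.plex == 2


# ------------------------------------------------------------------ filters


def _spacer(seq, **kw):
    kw.setdefault("category", "intergenic_negative")
    return Spacer(id=f"s_{seq[:6]}", sequence=seq, **kw)


@pytest.mark.parametrize(
    "seq,kwargs,expected_reason",
    [
        ("ACGACGACGACGACGACGACGAC", {}, None),  # 23 nt, clean
        ("ACGACGCGTCTCACGACGACGAC", {}, "restriction_site"),
        ("ACGACGGAGACGACGACGACGAC", {}, "restriction_site"),
        ("ACGACGTTTACGACGACGACGAC", {}, "polyT"),
        ("ACGACGACGACGACGACGACGAC", {"offtarget_match_flag": "MAX"}, "offtarget"),
        ("ACGACGACGACGACGACGACGAC", {"tier1_bin1_matches": 2}, "offtarget"),
        ("ACGACGACGACGACGACGACGAC", {"tier1_bin1_matches": 1}, None),
    ],
)
def test_filter_reason_codes(seq, kwargs, expected_reason):
    retained, rejected = filter_spacers([_spacer(seq, **kwargs)])
    if expected_reason is None:
        assert len(retained) == 1 and not rejected
    else:
        assert not retained
        assert rejected[0][1] == expected_reason


def test_filter_partitions_input_and_is_idempotent(spacer_pool):
    dirty = spacer_pool + [
        _spacer("ACGACGTTTACGACGACGAC"),
        _spacer("ACGCGTCTCACGACGACGAC"),
    ]
    retained, rejected = filter_spacers(dirty)
    assert len(retained) + len(rejected) == len(dirty)
    again, again_rejected = filter_spacers(retained)
    assert again == retained and not again_rejected


def test_efficacy_floor():
    sp = _spacer("ACGACGACGACGACGACGAC", on_target_efficacy=0.4)
    _, rejected = filter_spacers([sp], FilterConfig(min_efficacy=0.5))
    assert rejected[0][1] == "low_efficacy"


def test_non_dna_sequence_names_offending_record():
    with pytest.raises(ValueError, match="s_ACGXCG"):
        filter_spacers([_spacer("ACGXCGACGACGACGACGAC")])


# ----------------------------------------------------------------- assembly


def test_assemble_array_length_closed_form(dr6):
    spacers = random_spacers(3, length=23, seed=3)
    a3 = assign_direct_repeats(3)
    construct = assemble_array(spacers, a3)
    assert len(construct.sequence) == 4 * 19 + 3 * 23 == 145


def test_assemble_single_plex_is_wt_spacer_dr8():
    sp = random_spacers(1, length=23, seed=4)[0]
    construct = assemble_array([sp], assign_direct_repeats(1))
    assert construct.sequence == (
        DR_SEQUENCES["WT"] + sp.sequence + DR_SEQUENCES["DR8"]
    )
    assert len(construct.sequence) == 61


def test_assemble_empty_or_mismatched_plex_errors(dr6):
    with pytest.raises(ValueError):
        assemble_array([], dr6)
    with pytest.raises(ValueError):
        assemble_array(random_spacers(3, seed=5), dr6)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    plex=st.sampled_from(sorted(DR_ASSIGNMENTS)),
    seed=st.integers(0, 1000),
)
def test_assembled_array_roundtrips_by_dr_segmentation(plex, seed):
    """Splitting the sequence on the assigned DRs recovers the spacers."""
    assignment = assign_direct_repeats(plex)
    spacers = random_spacers(plex, length=20, seed=seed)
    construct = assemble_array(spacers, assignment)
    seq = construct.sequence
    recovered = []
    pos = len(assignment.ordered_drs[0].sequence)
    for dr in assignment.ordered_drs[1:]:
        nxt = seq.index(dr.sequence, pos)
        recovered.append(seq[pos:nxt])
        pos = nxt + len(dr.sequence)
    assert tuple(recovered) == construct.spacer_tuple
    assert pos == len(seq)


# ----------------------------------------------------------------- designs


def test_tiling_library_window_and_filters():
    inside = [
        Spacer(f"in{i}", s.sequence, "tss_targeting", target_id="G1",
               tss_offset=o)
        for i, (s, o) in enumerate(
            zip(random_spacers(4, seed=6), (-50, 0, 150, 300))
        )
    ]
    outside = [
        Spacer("out1", random_spacers(1, seed=7)[0].sequence,
               "tss_targeting", target_id="G1", tss_offset=400),
        Spacer("out2", random_spacers(1, seed=8)[0].sequence,
               "tss_targeting", target_id="G1", tss_offset=-51),
    ]
    dirty = Spacer("bad", "ACGACGTTTACGACGACGAC", "tss_targeting",
                   target_id="G1", tss_offset=10)
    lib = design_tiling_library(inside + outside + [dirty])
    assert {c.id for c in lib} == {"in0", "in1", "in2", "in3"}
    assert lib.plex_levels == {1}


def test_tiling_survivors_match_record_by_record_oracle():
    rng = np.random.default_rng(42)
    pool = random_spacers(80, seed=9)
    # brute-force oracle: re-apply window + filters per record
    candidates = [
        Spacer(
            s.id, s.sequence, "tss_targeting", target_id="G",
            tss_offset=int(rng.integers(-120, 420)),
            tier1_bin1_matches=int(rng.integers(0, 4)),
        )
        for s in pool
    ]
    lib = design_tiling_library(candidates)
    expected = {
        s.id
        for s in candidates
        if -50 <= s.tss_offset <= 300
        and s.tier1_bin1_matches <= 1
        and "TTT" not in s.sequence
        and "CGTCTC" not in s.sequence
        and "GAGACG" not in s.sequence
    }
    assert {c.id for c in lib} == expected


def test_sublibrary_a_counts_and_structure(spacer_pool):
    tests = random_spacers(3, seed=21, prefix="t")
    contexts = [spacer_pool[6 * i : 6 * i + 6] for i in range(5)]
    lib = design_sublibrary_A(tests, contexts)
    assert len(lib) == 3 * 6 * 5 == 90
    ids = {c.id for c in lib}
    assert len(ids) == 90
    # at the test position, the context spacer is replaced by the test spacer
    for c in lib:
        p = c.test_position
        assert c.spacers[p - 1].id.startswith("t")
        ctx_idx = int(c.context_set_id[3:]) - 1
        for q in range(6):
            if q != p - 1:
                assert c.spacers[q] == contexts[ctx_idx][q]


def test_sublibrary_a_requires_disjoint_test_and_context(spacer_pool):
    contexts = [spacer_pool[:6]]
    with pytest.raises(ValueError, match="disjoint"):
        design_sublibrary_A([spacer_pool[0]], contexts)


def test_sublibrary_b_enumeration_and_reversal():
    pool = random_spacers(15, seed=22, prefix="p")
    groups = [pool[3 * i : 3 * i + 3] for i in range(5)]
    lib = design_sublibrary_B(groups, pool)
    # 5 x C(15,3) x 2 = 4,550 before duplicate collapse; a forward array
    # never equals a reversed one here (front triples are ordered), so
    # only palindromic duplicates could collapse -- none with 15 distinct
    # spacers.
    assert 0 < len(lib) <= 5 * 455 * 2
    assert all(c.plex == 6 for c in lib)
    tuples = set(lib.index)
    # every emitted forward array has its exact reverse present too
    for t in itertools.islice(tuples, 200):
        assert t[::-1] in tuples


def test_sublibrary_b_warns_on_nonstandard_pool_size():
    pool = random_spacers(9, seed=23)
    groups = [pool[3 * i : 3 * i + 3] for i in range(3)]
    with pytest.warns(UserWarning, match="expected 15"):
        design_sublibrary_B(groups, pool)


def test_negative_control_sampling_counts_and_determinism(spacer_pool):
    inter = spacer_pool[:30]
    nt = random_spacers(
        30, seed=24, category="nontargeting_negative", prefix="nt"
    )
    lib1 = sample_negative_control_constructs(inter, nt, 15, 5, seed=7)
    lib2 = sample_negative_control_constructs(inter, nt, 15, 5, seed=7)
    assert len(lib1) == 20
    assert sorted(lib1.index) == sorted(lib2.index)
    inter_ids = {s.id for s in inter}
    for c in lib1:
        ids = set(c.spacer_ids)
        # no mixing of pools within a construct
        assert ids <= inter_ids or not (ids & inter_ids)


def test_negative_control_sampling_edge_cases(spacer_pool):
    lib = sample_negative_control_constructs(spacer_pool, [], 0, 0)
    assert len(lib) == 0
    with pytest.raises(ValueError, match="pool"):
        sample_negative_control_constructs(spacer_pool[:3], [], 1, 0, plex=6)


# --------------------------------------------- intergenic control regions


def test_intergenic_regions_toy_chromosome_tiling():
    regions = select_intergenic_control_regions(
        {"chr1": 10_000}, [], per_chrom=90
    )
    assert len(regions) == 10
    assert all(r.end - r.start == 1000 for r in regions)


def test_intergenic_regions_respect_padded_exclusions_bruteforce():
    chrom_lengths = {"chr1": 60_000}
    genes = [GenomicInterval("chr1", 25_000, 26_000)]
    dhs = [GenomicInterval("chr1", 50_000, 50_100)]
    regions = select_intergenic_control_regions(
        chrom_lengths, genes, dhs, per_chrom=1000, seed=1
    )
    assert regions
    # brute-force per-base oracle over padded exclusions
    excluded = np.zeros(60_000, dtype=bool)
    excluded[25_000 - 10_000 : 26_000 + 10_000] = True
    excluded[50_000 - 3_000 : 50_100 + 3_000] = True
    for r in regions:
        assert not excluded[r.start : r.end].any()


def test_intergenic_regions_drop_n_runs():
    seq = ["A"] * 10_000
    seq[2500:2525] = ["N"] * 25  # 25-N run inside the third fragment
    regions = select_intergenic_control_regions(
        {"chr1": 10_000}, [], sequences={"chr1": "".join(seq)}
    )
    assert len(regions) == 9
    assert all(not (r.start <= 2500 < r.end) for r in regions)


def test_intergenic_regions_per_chrom_cap():
    regions = select_intergenic_control_regions(
        {"chr1": 200_000}, [], per_chrom=90, seed=3
    )
    assert len(regions) == 90


# --------------------------------------------------- derived nontargeting


def test_derive_nontargeting_transformation_and_determinism():
    sources = random_spacers(10, length=20, seed=25)
    out1 = derive_nontargeting_spacers(sources, seed=5)
    out2 = derive_nontargeting_spacers(sources, seed=5)
    assert [s.sequence for s in out1] == [s.sequence for s in out2]
    for src, drv in zip(sources, out1):
        assert len(drv.sequence) == 23
        assert drv.sequence[:19] == src.sequence[1:20]


def test_derive_nontargeting_rejects_wrong_length():
    bad = random_spacers(1, length=21, seed=26)[0]
    with pytest.raises(ValueError, match=bad.id):
        derive_nontargeting_spacers([bad])


# ------------------------------------------------------------------ oligos


def test_oligo_pair_strands_are_reverse_complements(dr6, spacer_pool):
    construct = assemble_array(spacer_pool[:6], dr6)
    top, bottom = emit_cloning_oligos(
        construct, FlankConfig(), mode="oligo_pair"
    )
    duplex_top = top[4:]  # strip the 4-nt overhang
    assert bottom[4:] == revcomp(duplex_top)
    assert "CGTCTC" not in construct.sequence
    assert "GAGACG" not in construct.sequence


def test_gene_block_requires_flanks_with_bsmbi(dr6, spacer_pool):
    construct = assemble_array(spacer_pool[:6], dr6)
    with pytest.raises(ValueError, match="flank"):
        emit_cloning_oligos(construct, FlankConfig(), mode="gene_block")
    flanks = FlankConfig(
        five_prime="AAACGTCTCAAGAT", three_prime="AATTAGAGACGAAA"
    )
    block = emit_cloning_oligos(construct, flanks, mode="gene_block")
    assert construct.sequence in block


# ---------------------------------------------------------------- coverage


@pytest.mark.parametrize(
    "n,plex,expected", [(22, 4, 352), (1, 10, 1024), (0, 6, 0)]
)
def test_group_testing_coverage(n, plex, expected):
    assert group_testing_coverage(n, plex) == expected


def test_group_testing_coverage_rejects_negative():
    with pytest.raises(ValueError):
        group_testing_coverage(-1, 4)
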