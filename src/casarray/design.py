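"""Library design for multiplexed Cas12a CRISPRi screens.

Covers spacer filtering, array assembly, the three library archetypes
(TSS tiling singles, positional test/context 6-plex arrays, combinatorial
element-targeting 6-plex arrays), negative-control construct sampling,
intergenic control-region selection, cloning-oligo emission and the
group-testing coverage arithmetic.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .records import (
    DR_ASSIGNMENTS,
    ArrayConstruct,
    ConstructLibrary,
    DirectRepeatAssignment,
    OFFTARGET_MAX,
    Spacer,
    direct_repeat,
    revcomp,
    validate_dna,
)

__all__ = [
    "assign_direct_repeats",
    "FilterConfig",
    "filter_spacers",
    "assemble_array",
    "design_tiling_library",
    "design_sublibrary_A",
    "design_sublibrary_B",
    "sample_negative_control_constructs",
    "GenomicInterval",
    "select_intergenic_control_regions",
    "derive_nontargeting_spacers",
    "FlankConfig",
    "emit_cloning_oligos",
    "group_testing_coverage",
]

# BsmBI recognition site and its reverse complement; arrays are cloned by
# Golden Gate into a BsmBI-cut vector, so the insert must not contain it.
BSMBI_SITE = "CGTCTC"
BSMBI_SITE_RC = "GAGACG"


def assign_direct_repeats(
    plex: int,
    custom: Optional[Sequence[str]] = None,
) -> DirectRepeatAssignment:
    """Return the position-specific DR variants for a plex-N array.

    Supported plex levels are 1, 3, 4, 5, 6, 8 and 10; other levels
    require a ``custom`` list of plex+1 DR names (5'->3').
    """
    if custom is not None:
        names = tuple(custom)
    elif plex in DR_ASSIGNMENTS:
        names = DR_ASSIGNMENTS[plex]
    else:
        raise ValueError(
            f"no direct-repeat assignment for plex={plex}; supported levels "
            f"are {sorted(DR_ASSIGNMENTS)} (or pass a custom assignment)"
        )
    return DirectRepeatAssignment(
        plex=plex, ordered_drs=tuple(direct_repeat(n) for n in names)
    )


@dataclass(frozen=True)
class FilterConfig:
    """Spacer-sequence exclusion rules.

    polyT runs of ``polyt_run`` or more consecutive T's mimic the RNA
    Pol III terminator; restriction motifs would break Golden Gate
    cloning; the off-target rules reject any spacer flagged "MAX" in any
    tier/bin or with more than one tier-I bin-I genomic match.  The
    rules apply to spacer sequences only, never to direct repeats.
    """

    polyt_run: int = 3
    restriction_motifs: tuple[str, ...] = (BSMBI_SITE, BSMBI_SITE_RC)
    apply_offtarget_rules: bool = True
    max_tier1_bin1_matches: int = 1
    min_efficacy: Optional[float] = None


# Primary rejection reason codes in precedence order.
REASON_RESTRICTION = "restriction_site"
REASON_POLYT = "polyT"
REASON_OFFTARGET = "offtarget"
REASON_LOW_EFFICACY = "low_efficacy"


def _rejection_reason(sp: Spacer, config: FilterConfig) -> Optional[str]:
    seq = sp.sequence
    for motif in config.restriction_motifs:
        if motif in seq:
            return REASON_RESTRICTION
    if "T" * config.polyt_run in seq:
        return REASON_POLYT
    if config.apply_offtarget_rules:
        if sp.offtarget_match_flag == OFFTARGET_MAX:
            return REASON_OFFTARGET
        if (
            sp.tier1_bin1_matches is not None
            and sp.tier1_bin1_matches > config.max_tier1_bin1_matches
        ):
            return REASON_OFFTARGET
    if config.min_efficacy is not None:
        if (
            sp.on_target_efficacy is None
            or sp.on_target_efficacy < config.min_efficacy
        ):
            return REASON_LOW_EFFICACY
    return None


def filter_spacers(
    candidates: Iterable[Spacer],
    config: FilterConfig | None = None,
) -> tuple[list[Spacer], list[tuple[Spacer, str]]]:
    """Partition candidate spacers into (retained, rejected-with-reason).

    Each rejected spacer carries exactly one primary reason code; the
    precedence is restriction_site > polyT > offtarget > low_efficacy.
    Raises on non-DNA sequences, naming the offending record.
    """
    config = config or FilterConfig()
    retained: list[Spacer] = []
    rejected: list[tuple[Spacer, str]] = []
    for sp in candidates:
        sp.validate()
        reason = _rejection_reason(sp, config)
        if reason is None:
            retained.append(sp)
        else:
            rejected.append((sp, reason))
    return retained, rejected


def assemble_array(
    spacers: Sequence[Spacer],
    dr_assignment: DirectRepeatAssignment,
    construct_id: Optional[str] = None,
    *,
    test_position: Optional[int] = None,
    context_set_id: Optional[str] = None,
) -> ArrayConstruct:
    """Interleave DRs and spacers: DR0 + s1 + DR1 + ... + sN + DRN.

    Total length is 19*(plex+1) + sum of spacer lengths.
    """
    if len(spacers) == 0:
        raise ValueError("cannot assemble an array with zero spacers")
    if len(spacers) != dr_assignment.plex:
        raise ValueError(
            f"{len(spacers)} spacers but DR assignment is for "
            f"{dr_assignment.plex}-plex"
        )
    parts = [dr_assignment.ordered_drs[0].sequence]
    for sp, dr in zip(spacers, dr_assignment.ordered_drs[1:]):
        parts.append(sp.sequence)
        parts.append(dr.sequence)
    sequence = "".join(parts)
    if construct_id is None:
        construct_id = "_".join(s.id for s in spacers)
    return ArrayConstruct(
        id=construct_id,
        spacers=tuple(spacers),
        dr_assignment=dr_assignment,
        sequence=sequence,
        test_position=test_position,
        context_set_id=context_set_id,
    )


def design_tiling_library(
    candidate_sites: Iterable[Spacer],
    window: tuple[int, int] = (-50, 300),
    config: FilterConfig | None = None,
) -> ConstructLibrary:
    """Single-crRNA TSS tiling library.

    Retains candidates whose PAM position relative to the TSS lies in
    ``window`` (inclusive) and which pass the spacer filters; each
    survivor becomes a 1-plex construct (WT DR + spacer + DR8).
    """
    lo, hi = window
    in_window = [
        sp
        for sp in candidate_sites
        if sp.tss_offset is not None and lo <= sp.tss_offset <= hi
    ]
    retained, _ = filter_spacers(in_window, config)
    dr1 = assign_direct_repeats(1)
    lib = ConstructLibrary()
    for sp in retained:
        lib.add(assemble_array([sp], dr1, construct_id=sp.id))
    return lib


def design_sublibrary_A(
    test_spacers: Sequence[Spacer],
    context_sets: Sequence[Sequence[Spacer]],
    plex: int = 6,
) -> ConstructLibrary:
    """Positional test/context design.

    For every (test spacer, test position, context set) one construct is
    emitted: the context set's spacer at the test position is replaced
    by the test spacer.  Construct count = tests x plex x contexts.
    """
    dr = assign_direct_repeats(plex)
    test_ids = {s.id for s in test_spacers}
    for cs in context_sets:
        if len(cs) != plex:
            raise ValueError(
                f"each context set must have exactly {plex} spacers, "
                f"got {len(cs)}"
            )
        overlap = test_ids & {s.id for s in cs}
        if overlap:
            raise ValueError(
                f"test and context spacers must be disjoint; shared: "
                f"{sorted(overlap)}"
            )
    lib = ConstructLibrary()
    for t in test_spacers:
        for pos in range(1, plex + 1):
            for ci, ctx in enumerate(context_sets):
                spacers = list(ctx)
                spacers[pos - 1] = t
                cid = f"{t.id}|pos{pos}|ctx{ci + 1}"
                try:
                    lib.add(
                        assemble_array(
                            spacers,
                            dr,
                            construct_id=cid,
                            test_position=pos,
                            context_set_id=f"ctx{ci + 1}",
                        )
                    )
                except ValueError as exc:
                    raise ValueError(
                        f"design violation (duplicate spacer tuple) at {cid}"
                    ) from exc
    return lib


def design_sublibrary_B(
    element_groups: Sequence[Sequence[Spacer]],
    spacer_pool: Sequence[Spacer],
    back_mode: str = "unordered",
) -> ConstructLibrary:
    """Combinatorial element-targeting design.

    Each ordered 3-plex element group fills positions 1-3 of a 6-plex
    array; positions 4-6 are filled with every 3-spacer combination from
    the pool (unordered combinations by default, ordered permutations
    with ``back_mode='ordered'``).  Every array is additionally emitted
    with its spacer order reversed; identical tuples are collapsed.
    """
    import warnings

    if back_mode not in ("unordered", "ordered"):
        raise ValueError("back_mode must be 'unordered' or 'ordered'")
    if not element_groups or any(len(g) == 0 for g in element_groups):
        raise ValueError("element groups must be non-empty")
    if len(spacer_pool) != 15:
        warnings.warn(
            f"spacer pool has {len(spacer_pool)} spacers (expected 15); "
            "proceeding",
            stacklevel=2,
        )
    if back_mode == "unordered":
        back_triples = list(itertools.combinations(spacer_pool, 3))
    else:
        back_triples = list(itertools.permutations(spacer_pool, 3))

    dr = assign_direct_repeats(6)
    lib = ConstructLibrary()
    seen: set[tuple[str, ...]] = set()
    counter = 0
    for gi, group in enumerate(element_groups):
        for back in back_triples:
            forward = tuple(group) + tuple(back)
            for spacers in (forward, forward[::-1]):
                key = tuple(s.sequence for s in spacers)
                if key in seen:
                    continue
                seen.add(key)
                counter += 1
                lib.add(
                    assemble_array(
                        spacers, dr, construct_id=f"B{counter:05d}_g{gi + 1}"
                    )
                )
    return lib


def sample_negative_control_constructs(
    intergenic_pool: Sequence[Spacer],
    nontargeting_pool: Sequence[Spacer],
    n_intergenic: int,
    n_nontargeting: int,
    plex: int = 6,
    seed: int = 0,
) -> ConstructLibrary:
    """Randomly sample all-negative plex-N combinations from each pool.

    Each construct draws its spacers without replacement from a single
    pool (pools are never mixed within a construct); sampled spacer
    tuples are unique across the library.
    """
    rng = np.random.default_rng(seed)
    dr = assign_direct_repeats(plex)
    lib = ConstructLibrary()
    for label, pool, n in (
        ("intergenic", list(intergenic_pool), n_intergenic),
        ("nontargeting", list(nontargeting_pool), n_nontargeting),
    ):
        if n == 0:
            continue
        if len(pool) < plex:
            raise ValueError(
                f"{label} pool has {len(pool)} spacers; need >= {plex}"
            )
        seen: set[tuple[str, ...]] = set()
        made = 0
        while made < n:
            idx = rng.choice(len(pool), size=plex, replace=False)
            spacers = [pool[i] for i in idx]
            key = tuple(s.sequence for s in spacers)
            if key in seen or lib.lookup(key) is not None:
                continue
            seen.add(key)
            made += 1
            lib.add(
                assemble_array(
                    spacers, dr, construct_id=f"neg_{label}_{made:05d}"
                )
            )
    return lib


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end: {self.chrom}:"
                f"{self.start}-{self.end}"
            )


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivals:
        return []
    ivals = sorted(ivals)
    merged = [ivals[0]]
    for s, e in ivals[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def select_intergenic_control_regions(
    chrom_lengths: dict[str, int],
    gene_intervals: Sequence[GenomicInterval],
    dhs_intervals: Sequence[GenomicInterval] = (),
    *,
    gene_pad: int = 10_000,
    dhs_pad: int = 3_000,
    fragment: int = 1_000,
    per_chrom: int = 90,
    max_n_run: int = 20,
    sequences: Optional[dict[str, str]] = None,
    seed: int = 0,
) -> list[GenomicInterval]:
    """Select intergenic 1-kb fragments for negative-control targeting.

    Removes everything within ``gene_pad`` of a gene or ``dhs_pad`` of a
    DNase hypersensitive site, tiles the remainder into ``fragment``-bp
    pieces, drops fragments containing a run of ``max_n_run`` or more Ns
    (when sequences are given) and samples up to ``per_chrom`` fragments
    per chromosome.
    """
    rng = np.random.default_rng(seed)
    excl: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for iv, pad in itertools.chain(
        ((g, gene_pad) for g in gene_intervals),
        ((d, dhs_pad) for d in dhs_intervals),
    ):
        if iv.chrom not in chrom_lengths:
            continue
        L = chrom_lengths[iv.chrom]
        excl[iv.chrom].append((max(0, iv.start - pad), min(L, iv.end + pad)))

    result: list[GenomicInterval] = []
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        merged = _merge_intervals(excl[chrom])
        # complement of exclusions within [0, L)
        free: list[tuple[int, int]] = []
        cursor = 0
        for s, e in merged:
            if s > cursor:
                free.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < L:
            free.append((cursor, L))
        frags: list[GenomicInterval] = []
        for s, e in free:
            for start in range(s, e - fragment + 1, fragment):
                frags.append(GenomicInterval(chrom, start, start + fragment))
        if sequences is not None and chrom in sequences:
            n_run = "N" * max_n_run
            seq = sequences[chrom].upper()
            frags = [f for f in frags if n_run not in seq[f.start : f.end]]
        if len(frags) > per_chrom:
            idx = sorted(rng.choice(len(frags), size=per_chrom, replace=False))
            frags = [frags[i] for i in idx]
        result.extend(frags)
    return result


def derive_nontargeting_spacers(
    source_20nt_spacers: Sequence[Spacer],
    seed: int = 0,
) -> list[Spacer]:
    """Convert 20-nt Cas9-style non-targeting spacers to 23-nt Cas12a ones.

    Drops the first base (the Pol III +1 G) and appends a random 4-mer
    to the 3' end, yielding 23-nt spacers.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    out: list[Spacer] = []
    for sp in source_20nt_spacers:
        if len(sp.sequence) != 20:
            raise ValueError(
                f"source spacer {sp.id!r} is {len(sp.sequence)} nt; "
                "expected exactly 20"
            )
        tail = "".join(rng.choice(bases, size=4))
        out.append(
            Spacer(
                id=f"{sp.id}_as",
                sequence=sp.sequence[1:] + tail,
                category="nontargeting_negative",
            )
        )
    return out


@dataclass(frozen=True)
class FlankConfig:
    """Vector flanks for cloning-oligo emission.

    For gene-block mode the flanks must carry the type-IIS (BsmBI)
    recognition site so the vector can excise itself; for annealed
    oligo-pair mode the 4-nt single-stranded overhangs are ligated into
    the pre-cut vector.
    """

    five_prime: str = ""
    three_prime: str = ""
    top_overhang: str = "AGAT"
    bottom_overhang: str = "AATT"


def emit_cloning_oligos(
    construct: ArrayConstruct,
    flank_config: FlankConfig,
    mode: str = "gene_block",
):
    """Emit cloning material for an assembled array.

    ``gene_block`` returns a single double-stranded fragment sequence
    (5' flank + array + 3' flank); ``oligo_pair`` returns (top, bottom)
    annealing oligos whose strands are exact reverse complements over
    the duplex (array) region, with Golden Gate overhangs prepended.
    """
    internal = construct.sequence
    for motif in (BSMBI_SITE, BSMBI_SITE_RC):
        if motif in internal:
            raise ValueError(
                f"construct {construct.id!r} contains internal restriction "
                f"site {motif}; it should have been filtered out"
            )
    if mode == "gene_block":
        if not flank_config.five_prime or not flank_config.three_prime:
            raise ValueError("gene-block mode requires non-empty flanks")
        for flank, side in (
            (flank_config.five_prime, "5'"),
            (flank_config.three_prime, "3'"),
        ):
            validate_dna(flank, who=f"{side} flank")
            if BSMBI_SITE not in flank and BSMBI_SITE_RC not in flank:
                raise ValueError(
                    f"{side} flank lacks the BsmBI recognition site"
                )
        return flank_config.five_prime + internal + flank_config.three_prime
    if mode == "oligo_pair":
        top = flank_config.top_overhang + internal
        bottom = flank_config.bottom_overhang + revcomp(internal)
        return top, bottom
    raise ValueError("mode must be 'gene_block' or 'oligo_pair'")


def group_testing_coverage(n_arrays: int, plex: int) -> int:
    """Number of spacer combinations interrogated by group testing.

    Each plex-N array indirectly tests all 2^N subsets of its spacers,
    so n_arrays arrays cover up to n_arrays * 2^plex combinations.
    """
    if n_arrays < 0 or plex < 0:
        raise ValueError("n_arrays and plex must be non-negative")
    return n_arrays * (2**plex)
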