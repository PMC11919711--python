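"""Synthetic data for pooled Cas12a CRISPRi screens.

Simulates every data modality the analysis consumes, with ground truth:

* pooled fitness screens -- construct abundances, multiplicative
  per-doubling growth, multinomial sequencing counts;
* array-spanning paired reads -- including lentiviral-recombination
  chimeras (spacer suffix swapped at a DR junction), PCR by-product
  reads, substitution errors and staggered read starts;
* amplicon reads with site-localised indels;
* single-cell flow-cytometry expression distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .design import FilterConfig, _rejection_reason
from .records import ArrayConstruct, ConstructLibrary, Spacer, revcomp

__all__ = [
    "random_spacers",
    "simulate_initial_abundance",
    "simulate_growth",
    "simulate_counts",
    "ScreenSimParams",
    "simulate_screen",
    "ReadSimParams",
    "SimulatedFragment",
    "simulate_array_reads",
    "AmpliconSimParams",
    "simulate_amplicon_reads",
    "FlowSimParams",
    "simulate_flow_expression",
]

_BASES = np.array(list("ACGT"))


def random_spacers(
    n: int,
    length: int = 20,
    seed: int = 0,
    category: str = "intergenic_negative",
    prefix: str = "sp",
    **spacer_kwargs,
) -> list[Spacer]:
    """Generate n random spacers that pass the default sequence filters.

    Rejection-samples until each candidate is free of polyT runs and
    restriction motifs, and de-duplicates sequences.
    """
    rng = np.random.default_rng(seed)
    cfg = FilterConfig()
    out: list[Spacer] = []
    seen: set[str] = set()
    while len(out) < n:
        seq = "".join(rng.choice(_BASES, size=length))
        if seq in seen:
            continue
        sp = Spacer(
            id=f"{prefix}{len(out) + 1:04d}",
            sequence=seq,
            category=category,
            **spacer_kwargs,
        )
        if _rejection_reason(sp, cfg) is None:
            seen.add(seq)
            out.append(sp)
    return out


def simulate_initial_abundance(
    n_constructs: int,
    abundance_model: str = "uniform",
    sigma: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Initial relative abundances (non-negative, summing to 1)."""
    if n_constructs < 1:
        raise ValueError("library must be non-empty")
    if abundance_model == "uniform":
        a = np.full(n_constructs, 1.0 / n_constructs)
    elif abundance_model == "lognormal":
        rng = np.random.default_rng(seed)
        a = rng.lognormal(mean=0.0, sigma=sigma, size=n_constructs)
        a /= a.sum()
    else:
        raise ValueError("abundance_model must be 'uniform' or 'lognormal'")
    return a


def simulate_growth(
    abundance: np.ndarray,
    gamma_truth: np.ndarray,
    doublings: float,
) -> np.ndarray:
    """Relative growth over D population doublings.

    Each construct's relative abundance is multiplied by 2^(gamma * D)
    and the vector renormalised, so the log2 ratio of any construct to
    a gamma=0 reference changes by exactly gamma * D.
    """
    if doublings <= 0:
        raise ValueError("doublings must be > 0")
    a = np.asarray(abundance, dtype=float) * np.exp2(
        np.asarray(gamma_truth, dtype=float) * doublings
    )
    return a / a.sum()


def simulate_counts(
    abundance: np.ndarray, depth: int, seed: int = 0
) -> np.ndarray:
    """Multinomial sequencing counts at the given read depth."""
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth == 0:
        return np.zeros(len(abundance), dtype=np.int64)
    rng = np.random.default_rng(seed)
    return rng.multinomial(depth, np.asarray(abundance, dtype=float))


@dataclass
class ScreenSimParams:
    """Conditions of a simulated pooled fitness screen.

    Defaults follow a two-replicate screen read at 10^6 fragments per
    sample over ~10 population doublings, in line with deep pooled
    fitness screens; negative-control constructs carry gamma = 0.
    """

    doublings: float = 10.0
    depth: int = 1_000_000
    abundance_model: str = "lognormal"
    sigma: float = 0.5
    n_replicates: int = 2
    shared_t0: bool = False
    seed: int = 0


def simulate_screen(
    construct_ids: Sequence[str],
    gamma_truth: Mapping[str, float],
    params: ScreenSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a T0/Tfinal x replicates count table.

    Returns ``(counts, sample_meta)``: counts indexed by construct with
    one column per sample; sample_meta has columns sample, timepoint,
    replicate, total_doublings.
    """
    ids = list(construct_ids)
    gammas = np.array([gamma_truth.get(c, 0.0) for c in ids])
    a0 = simulate_initial_abundance(
        len(ids), params.abundance_model, params.sigma, seed=params.seed
    )
    afinal = simulate_growth(a0, gammas, params.doublings)
    counts: dict[str, np.ndarray] = {}
    meta_rows = []
    for rep in range(1, params.n_replicates + 1):
        t0_seed = params.seed + 1 if params.shared_t0 else params.seed + rep
        t0_name = f"T0_rep{rep}"
        counts[t0_name] = simulate_counts(a0, params.depth, seed=t0_seed)
        meta_rows.append((t0_name, "T0", rep, params.doublings))
        tf_name = f"Tfinal_rep{rep}"
        counts[tf_name] = simulate_counts(
            afinal, params.depth, seed=params.seed + 100 + rep
        )
        meta_rows.append((tf_name, "Tfinal", rep, params.doublings))
    counts_df = pd.DataFrame(counts, index=pd.Index(ids, name="construct"))
    meta = pd.DataFrame(
        meta_rows,
        columns=["sample", "timepoint", "replicate", "total_doublings"],
    )
    return counts_df, meta


@dataclass
class ReadSimParams:
    """Sequencing-read simulation settings for array libraries.

    ``recombination_rate`` is the per-fragment probability of a
    lentiviral chimera (suffix swapped with another construct at a
    uniformly chosen DR junction); its true value in screens is low and
    uncertain, so the default is a nominal 0.01.  ``byproduct_rate``
    models unmappable PCR by-products as random-sequence fragments.
    """

    read_length: int = 250
    error_rate: float = 0.0
    recombination_rate: float = 0.01
    byproduct_rate: float = 0.0
    stagger_range: int = 8
    five_flank: str = "GTGGAAAGGACGAAACACCG" + "TTGTGGAAAGGACGAAACAC"
    three_flank: str = "TTTTTTAAGCTTGGCGTAACTAGATCTTGAGACAAATGGC"
    seed: int = 0


@dataclass
class SimulatedFragment:
    """One simulated read pair with its ground-truth label."""

    read_id: str
    r1: str
    r2: str
    truth: str  # 'construct' | 'chimera' | 'byproduct'
    construct_id: Optional[str] = None
    parents: Optional[tuple[str, str]] = None
    junction: Optional[int] = None
    spacer_tuple: Optional[tuple[str, ...]] = None


def _apply_errors(seq: str, error_rate: float, rng) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < error_rate
    if not hit.any():
        return seq
    idx = np.flatnonzero(hit)
    for i in idx:
        cur = arr[i].decode()
        choices = [b for b in "ACGT" if b != cur]
        arr[i] = rng.choice(choices).encode()
    return arr.tobytes().decode()


def simulate_array_reads(
    library: ConstructLibrary,
    counts: Mapping[str, int],
    params: ReadSimParams,
) -> list[SimulatedFragment]:
    """Simulate paired reads spanning array constructs.

    R1 reads the fragment 5'->3' from a 0-8 nt staggered start; R2 reads
    the reverse complement from the 3' end.  A chimeric fragment takes
    the spacer prefix of one construct up to a uniformly chosen DR
    junction and the suffix of another; errors are substitutions only.
    """
    constructs = list(library)
    if not constructs:
        raise ValueError("empty library")
    min_span = min(len(c.sequence) for c in constructs)
    if params.read_length < 19 + 19:
        raise ValueError(
            "read_length shorter than the minimal informative span "
            "(one DR + one spacer)"
        )
    rng = np.random.default_rng(params.seed)
    by_id = {c.id: c for c in constructs}
    dr = constructs[0].dr_assignment
    plex = dr.plex

    def fragment_for(spacers: tuple[str, ...]) -> str:
        parts = [dr.ordered_drs[0].sequence]
        for s, d in zip(spacers, dr.ordered_drs[1:]):
            parts.append(s)
            parts.append(d.sequence)
        return params.five_flank + "".join(parts) + params.three_flank

    out: list[SimulatedFragment] = []
    rid = 0
    for cid, n in counts.items():
        c = by_id[cid]
        for _ in range(int(n)):
            rid += 1
            u = rng.random()
            if u < params.byproduct_rate:
                L = len(params.five_flank) + len(c.sequence) + len(
                    params.three_flank
                )
                frag = "".join(rng.choice(_BASES, size=L))
                rec = SimulatedFragment(
                    read_id=f"frag{rid:07d}", r1="", r2="", truth="byproduct"
                )
            elif (
                u < params.byproduct_rate + params.recombination_rate
                and plex >= 2
                and len(constructs) >= 2
            ):
                # a chimera is a novel spacer combination; redraw partner
                # and junction if the swap reproduces a designed tuple
                for _attempt in range(50):
                    partner = constructs[int(rng.integers(len(constructs)))]
                    while partner.id == cid and len(constructs) > 1:
                        partner = constructs[
                            int(rng.integers(len(constructs)))
                        ]
                    j = int(rng.integers(1, plex))  # junction after spacer j
                    spacers = c.spacer_tuple[:j] + partner.spacer_tuple[j:]
                    if library.lookup(spacers) is None:
                        break
                else:
                    raise RuntimeError(
                        "library too dense to form a novel chimera"
                    )
                frag = fragment_for(spacers)
                rec = SimulatedFragment(
                    read_id=f"frag{rid:07d}",
                    r1="",
                    r2="",
                    truth="chimera",
                    parents=(cid, partner.id),
                    junction=j,
                    spacer_tuple=spacers,
                )
            else:
                frag = fragment_for(c.spacer_tuple)
                rec = SimulatedFragment(
                    read_id=f"frag{rid:07d}",
                    r1="",
                    r2="",
                    truth="construct",
                    construct_id=cid,
                    spacer_tuple=c.spacer_tuple,
                )
            s1 = int(rng.integers(0, params.stagger_range + 1))
            s2 = int(rng.integers(0, params.stagger_range + 1))
            r1 = frag[s1 : s1 + params.read_length]
            rc = revcomp(frag)
            r2 = rc[s2 : s2 + params.read_length]
            rec.r1 = _apply_errors(r1, params.error_rate, rng)
            rec.r2 = _apply_errors(r2, params.error_rate, rng)
            out.append(rec)
    return out


@dataclass
class AmpliconSimParams:
    """Amplicon sequencing with site-localised indels.

    Each read spans the full amplicon; at cut site k it independently
    acquires an indel with probability per_site_indel_freq[k], centred
    at the site with a size drawn from ``indel_sizes`` (probability
    ``indel_size_probs``; negative = deletion span, positive =
    insertion, which occupies a single base position in amplicon
    coordinates).
    """

    amplicon_length: int = 340
    cut_sites: tuple[int, ...] = (114, 226)
    per_site_indel_freq: tuple[float, ...] = (0.05, 0.05)
    indel_sizes: tuple[int, ...] = (-10, -5, -2, -1, 1, 2)
    indel_size_probs: tuple[float, ...] = (0.1, 0.2, 0.25, 0.25, 0.15, 0.05)
    n_reads: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if len(self.cut_sites) != len(self.per_site_indel_freq):
            raise ValueError("one indel frequency per cut site required")
        for s in self.cut_sites:
            if not 0 <= s < self.amplicon_length:
                raise ValueError(f"cut site {s} outside amplicon")
        for f in self.per_site_indel_freq:
            if not 0.0 <= f <= 1.0:
                raise ValueError("indel frequencies must be in [0, 1]")


def simulate_amplicon_reads(params: AmpliconSimParams) -> pd.DataFrame:
    """Simulate aligned amplicon reads.

    Returns a table with one row per indel event: columns read_id,
    indel_start, indel_end (0-based half-open, amplicon coordinates),
    type; reads without indels appear with null start/end and type
    'none' so the total read count is recoverable.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    sizes = np.array(params.indel_sizes)
    size_p = np.array(params.indel_size_probs, dtype=float)
    size_p = size_p / size_p.sum()
    rows = []
    for i in range(params.n_reads):
        read_id = f"amp{i:07d}"
        any_indel = False
        for site, freq in zip(params.cut_sites, params.per_site_indel_freq):
            if rng.random() >= freq:
                continue
            any_indel = True
            size = int(rng.choice(sizes, p=size_p))
            if size < 0:  # deletion centred at the cut site
                half = -size // 2
                start = max(0, site - half)
                end = min(params.amplicon_length, start - size)
            else:  # insertion occupies the base at the cut site
                start, end = site, site + 1
            rows.append(
                (
                    read_id,
                    start,
                    end,
                    "deletion" if size < 0 else "insertion",
                )
            )
        if not any_indel:
            rows.append((read_id, pd.NA, pd.NA, "none"))
    return pd.DataFrame(
        rows, columns=["read_id", "indel_start", "indel_end", "type"]
    )


@dataclass
class FlowSimParams:
    """Single-cell flow-cytometry expression simulation.

    Control cells draw log-normal expression (mu, sigma on the natural
    log scale); knockdown scales the target population's median by
    (1 - knockdown_fraction) under the same multiplicative noise.
    """

    n_cells: int = 10_000
    knockdown_fraction: float = 0.0
    mu: float = 7.0
    sigma: float = 0.6
    seed: int = 0


def simulate_flow_expression(
    params: FlowSimParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (target_population, control_population) expression vectors."""
    if params.n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0.0 <= params.knockdown_fraction <= 1.0:
        raise ValueError("knockdown_fraction must be in [0, 1]")
    rng = np.random.default_rng(params.seed)
    control = rng.lognormal(params.mu, params.sigma, params.n_cells)
    if params.knockdown_fraction >= 1.0:
        target = np.zeros(params.n_cells)
    else:
        target = rng.lognormal(
            params.mu + np.log1p(-params.knockdown_fraction),
            params.sigma,
            params.n_cells,
        )
    return target, control
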