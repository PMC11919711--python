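# casarray

Design, simulation and analysis of **multiplexed Cas12a CRISPRi pooled
screens** built on crRNA arrays.

Cas12a processes a single transcript of alternating 19-nt direct repeats
(DRs) and 19–23-nt spacers into multiple guides, so one lentiviral
construct can direct CRISPRi against up to ten genomic sites per cell.
Assigning a *distinct DR variant to each array position* suppresses
recombination between repeated sequences during lentiviral delivery, and
those position-specific DRs double as exact anchors for mapping
sequencing reads back to constructs. Because each N-plex array
indirectly interrogates all 2^N subsets of its spacers, libraries of
such arrays implement a *group testing* strategy for combinatorial
perturbation screens.

`casarray` is aimed at people who build or analyse such screens. It
provides:

- **Library design** (`casarray.design`) — spacer filtering (polyT runs,
  BsmBI sites, off-target annotations), array assembly with the
  position-specific DR variants, TSS-tiling single-crRNA libraries,
  positional test/context 6-plex libraries, combinatorial
  element-targeting 6-plex libraries, negative-control construct
  sampling, intergenic control-region selection, cloning-oligo emission
  and group-testing coverage arithmetic.
- **Synthetic data** (`casarray.simulate`) — pooled fitness screens with
  known per-construct fitness effects, paired array reads with
  recombination chimeras / PCR by-products / substitution errors /
  staggered starts, amplicon reads with site-localised indels, and
  flow-cytometry expression distributions.
- **Exact-match mapping** (`casarray.mapping`) — DR-anchored
  segmentation of paired array reads into per-position spacers with
  mapped / recombinant / unmapped classification, and single-spacer
  counting, both under a strict perfect-match contract.
- **Screen statistics** (`casarray.analysis`) — RPM coverage filtering,
  the per-doubling fitness score γ, percentile hit calling, TSS
  metagene profiles, test/context aggregation and recall, group-testing
  category summaries, MOI, and flow-cytometry knockdown metrics.
- **Indel modelling** (`casarray.indel`) — per-base indel fractions over
  amplicons and a copy-number-aware upper bound on indel-driven
  expression knockdown.

## The fitness score

For each construct and screen replicate, with read counts normalised to
reads per million (RPM, after a pseudocount of 1),

```
γ = log2( (RPM_final / negctrl_median_RPM_final)
        / (RPM_initial / negctrl_median_RPM_initial) ) / total_doublings
```

γ is the fractional cell fitness defect per population doubling:
γ = −0.1 means the construct's cells are depleted two-fold (one log2
unit) every ten doublings relative to the median negative control.
Hits are constructs whose γ falls below the 5th percentile of the
negative-control score distribution.

## Worked example

```python
import numpy as np
from casarray import (
    assign_direct_repeats, assemble_array, random_spacers,
    simulate_screen, ScreenSimParams, fitness_score, call_hits,
    group_testing_coverage,
)

# assemble a 6-plex array with the position-specific DR variants
spacers = random_spacers(6, length=20, seed=7)
construct = assemble_array(spacers, assign_direct_repeats(6), "demo")
print(construct.plex, len(construct.sequence))   # 6 253

# simulate a 100-construct screen (40 negative controls) and score it
ids = [f"c{i}" for i in range(100)]
negctrl = ids[:40]
rng = np.random.default_rng(0)
truth = {c: float(g) for c, g in zip(ids[40:], rng.uniform(-0.4, 0, 60))}
counts, meta = simulate_screen(
    ids, truth, ScreenSimParams(doublings=10.0, depth=10**6, seed=1)
)
table = fitness_score(counts, meta, negctrl)
flags, thr = call_hits(table["gamma_mean"], table.loc[negctrl, "gamma_mean"])
print(round(table.loc["c40", "gamma_mean"], 3))  # -0.148 (truth -0.145)
print(int(flags[ids[40:]].sum()))                # 59 of 60 recovered
print(group_testing_coverage(22, 4))             # 352
```

The estimated γ of construct `c40` (−0.148) recovers its simulated
fitness effect (−0.145) to within sampling noise at a read depth of
10^6; 59 of the 60 constructs with non-zero effects fall below the
negative-control 5th-percentile threshold (−0.0036); and a well-based
experiment of 22 4-plex arrays indirectly tests 22 × 2^4 = 352 spacer
combinations.

A `casarray` console script exposes the same stages
(`casarray design …`, `casarray simulate …`, `casarray map …`,
`casarray score`, `casarray indel …`; see `casarray --help`).

## Layout

```
src/casarray/     records, design, simulate, mapping, analysis, indel, io, cli
tests/            pytest suite (unit, property and acceptance tests)
docs/methods.md   models, assumptions, defaults and limitations
scripts/          acceptance.py
```
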