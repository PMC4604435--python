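# evcargo

Small-RNA fragment profiling and extracellular-vesicle (EV) cargo
enrichment, rebuilt as a tested Python pipeline that runs entirely on
synthetic data.

## The problem

Cells export RNA inside extracellular vesicles. Sequencing the cargo of
EVs from a primary fibroblast line (BJ) and a leukemia line (K562) shows
that a single Y RNA gene, *RNY5*, dominates the EV small-RNA pool — ~35%
of assigned reads in BJ EVs and ~48% in K562 EVs, versus 0.1–0.2% in the
source cells (a ~196x / ~68x rpm enrichment) — and that it travels not as
the 83-nt primary transcript but as processed fragments: 5'-anchored
pieces ending at positions 23, 29 and 31, and a 3'-side piece starting at
position 52. Reproducing those numbers computationally requires a chain of
small but consequential decisions: a mapping contract (≤5 mismatches, ≤10
loci), union-mode counting of unique mappers, an rpm normalisation, and a
policy for short 5' fragments that multimap to *RNY5* pseudogenes. This
package implements that chain for anyone who wants to study, teach or
stress-test fragment-profiling analyses with known ground truth.

## What is inside

| module | role |
|---|---|
| `evcargo.sequences` | the printed oligo panel (83-mer, 31-mer, 23-mer, scrambled/motif variants, Northern probe) and motif/fragment operations |
| `evcargo.synthetic_data` | toy genome with pseudogene decoys, cell/EV library simulator anchored at the measured abundances, in-vitro processing rule table, cytometry event generator |
| `evcargo.toy_aligner` | exhaustive ungapped aligner honouring the mapping contract, SAM output with NH tags |
| `evcargo.counting` | union-mode counting, rpm, RNA-family tables, EV/cell enrichment and ratios |
| `evcargo.fragment_profile` | per-gene start/stop rpm histograms with frequent-position calling and a pseudogene-aware multimapper policy |
| `evcargo.cytometry` | Hoechst/YO-PRO-1 double-positive gating, condition comparison, dose-response tables |
| `evcargo.pipeline`, `evcargo.cli` | one-command orchestration (`evcargo run-all`) |

Core statistic: for gene *g* in a library with `U` uniquely mapping reads,

    rpm(g) = count(g) / U x 1e6,

where `count(g)` is the number of unique mappers whose alignment overlaps
*g* and no other gene. Fragment profiling tabulates transcript-coordinate
read 5'/3' ends weighted in rpm and calls positions above 1000 rpm
"frequent"; multimapping 5' fragments are attributed to *RNY5* when every
reported locus lies in the gene or its pseudogene set.

## Worked example

```python
from evcargo.synthetic_data import build_reference, default_profile, simulate_library
from evcargo.toy_aligner import align_library
from evcargo.counting import count_genes, enrichment
from evcargo.fragment_profile import profile_gene

ref = build_reference(seed=1)
for name, seed in [("bj_ev", 11), ("bj_cell", 12)]:
    profile = default_profile(name, ref, read_count=1_000_000)
    simulate_library(profile, ref, f"{name}.fastq", seed=seed)
    align_library(f"{name}.fastq", ref, f"{name}.sam")

ev = count_genes("bj_ev.sam", ref.annotations, "bj_ev")
cell = count_genes("bj_cell.sam", ref.annotations, "bj_cell")
print("RNY5 share of assigned reads:",
      round(100 * ev.counts["RNY5"] / ev.stats["counted"], 2), "%")
print("EV/cell enrichment:", round(enrichment(ev, cell, "RNY5"), 1), "fold")

prof = profile_gene("bj_ev.sam", ref.annotations, "RNY5", ref.pseudogene_set)
print("frequent starts:", sorted(prof.frequent_starts))
print("frequent stops:", sorted(prof.frequent_stops))
```

prints

```
RNY5 share of assigned reads: 34.98 %
EV/cell enrichment: 204.7 fold
frequent starts: [1, 52]
frequent stops: [23, 29, 31, 83]
```

Read it as: the simulated BJ-EV library hands the pipeline back the 35%
RNY5 share and ~196-fold enrichment it was anchored at (the 204.7 here is
within the ~3% sampling error of the ~950-read whole-cell RNY5 count), and
the fragment histogram recovers exactly the processing geometry — reads
start at the transcript 5' end and at position 52, and stop at 23/29/31
(the processed forms) and 83 (full length). The stops at 23 and 29 only
appear because multimapping reads explained by the pseudogene set are
included; under `policy="exclude_multimappers"` they vanish, which is the
point of the policy.

The same library can be gated and dosed on the cytometry side:

```
$ evcargo simulate-cytometry --condition bj_plus_k562_ev_rna --seed 5 --out ev.tsv
bj_plus_k562_ev_rna: 10000 events -> ev.tsv
$ evcargo gate --events ev.tsv
condition  events=10000  hoechst_pos=9475  double_pos=1974  percent_dead=20.83
```

20.83% against the configured 20.5% truth: a 9475-cell binomial draw.

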