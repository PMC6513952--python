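# chromstate

Event-based stochastic simulator of Polycomb/Trithorax (PcG/TrxG) chromatin
regulation on an array of half-nucleosomes, with the analyses built on top of
it: category time courses, 144-state occupancy landscapes, bistability
classification and phase-diagram parameter sweeps.

## Model

Each half-nucleosome (one H3 + one H2A tail) occupies one of 12 modification
states built from three sites: H3K27 (unmodified / acetylated /
trimethylated, with acetylation and trimethylation mutually exclusive), a
fused H3K4/K36 methylation site, and H2A ubiquitination. Position-paired
halves form whole nucleosomes (144 ordered states), classified into six
categories by their balance of active (K27ac, K4/36me) versus silent
(K27me3, H2Aub) marks: active-only, three bivalent grades, silent-only and
unmodified.

Dynamics follow an event-based kinetic Monte Carlo scheme with four
competing move channels: recruited conversions (a reader complex bound to
marks on one half writes or erases one mark on another, subject to
inhibition rules), a generic direct-conversion channel (rate `beta`), and
direct deacetylation (NURD) and deubiquitination (PR-DUB) channels.
Seven recruited complexes are modelled (TRXG, TRXG:UTX, TRXG:CBP, PRC1,
PRC2, PRC2:KDM, PRC2:KDM:NURD); in compound complexes only the last-listed
part is catalytic. Optional replication resets each half to the unmodified
state with probability 1/2 at fixed intervals.

## CLI

```bash
# run one simulation (TOML config; keys = SimulationConfig fields or the
# enzyme knobs trxg/utx/cbp/prc1/prc2/kdm/nurd/prdub)
chromstate run --config run.toml --seed 1 --out traj.tsv

# summarise a trajectory (category averages, regime call, co-occurrence,
# 12x12 landscape)
chromstate analyze --traj traj.tsv --out summary.json

# 1- or 2-parameter phase-diagram sweep
chromstate sweep --spec sweep.toml --out phases.tsv

# audit tables and synthetic fixtures
chromstate states dump
chromstate rules dump
chromstate fixture --epochs 100,100,100,100 --out fixture.tsv
```

Example `run.toml`:

```toml
duration = 50000.0
seed = 7
nurd = 0.5        # sets both the direct deacetylation rate and the
                  # recruited NURD-compound multiplier
prdub = 0.15
```

Trajectories are TSV (time, N half-state indices, six category counts) with
`.replication.tsv` and `.manifest.json` sidecars; the manifest echoes the
full config so a run can be reproduced exactly.

## Package layout

- `chromstate.states` — the 12 half states, index mapping, whole-nucleosome
  categories
- `chromstate.rules` — recruiter sets, enzyme action table, direct
  conversion channels
- `chromstate.engine` — configuration, the update loop (numba kernel in
  `chromstate._kernel`), replication, trajectory recording
- `chromstate.analysis` — occupancy series, landscapes, regime
  classification, mark co-occurrence statistics
- `chromstate.sweep` — grid sweeps, boundary scans, reference-regime
  discovery
- `chromstate.io` / `chromstate.cli` — config parsing, TSV/JSON round
  tripping, telegraph fixtures, command-line interface
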