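# poremap

Spatial heat maps of molecular importance from MD trajectories of liquids
(lipid bilayers, solvent). The pipeline transforms time-domain trajectory data
into per-residue rankings of how strongly each molecule's local distance
geometry is tied to a global "activity" of the system — the smoothed rate of
contact-forming/-breaking events in a cutoff graph, or a unit-cell dimension —
as applied to membrane electropore formation.

Pipeline stages:

1. **trajio** — read multi-model PDB / multi-frame GRO trajectories
   (orthorhombic cells only, Angstrom/ps internally), select one
   representative site per residue (e.g. lipid phosphorus, water oxygen),
   trim/stride time windows, write B-factor annotated structures.
2. **geometry** — minimum-image pair distances under periodic boundaries with
   per-frame boxes, culling of pairs to those ever within a
   significant-interaction cutoff, non-negative rate series |Δd|/Δt.
3. **activity** — two-cutoff hysteresis event detection (buffer zone
   suppresses recrossing noise), Gaussian-kernel event-rate smoothing, and
   box-dimension activity.
4. **dependence** — Pearson cross-correlation (negatives zeroed as noise
   floor) or plug-in mutual information via adaptive-bandwidth KDE
   (Abramson square-root bandwidths on a whitened joint kernel; robust to
   activities that are exactly zero over part of the window).
5. **heatmap** — masked column-mean compression of the positive symmetric
   dependence matrix to per-residue heat, ranking, TSV export.
6. **synthetic** — seeded toy pore-formation trajectories with ground truth
   (pore-lining sites, onset time), plus estimator fixtures.

## CLI

Generate a synthetic poration trajectory, compute activities, then a heat map:

```sh
poremap simulate --seed 1 --out sim
poremap -v activity -i sim/traj.pdb --dt 10 --box-axes z --out act
poremap -v heatmap -i sim/traj.pdb --dt 10 -a act/breaking.tsv \
        --method mutual_information --cull 15 --frame 499 --out hm
```

Key options (defaults follow the lipid-phosphorus coarse-graining rules of
thumb): hysteresis cutoffs `--low 11 --high 13` (Angstrom), smoothing
`--sigma auto` (5% of the window length), `--cull` for the
significant-interaction cutoff on pair selection, `--one-based` to give frame
windows in 1-based numbering. `heatmap` writes `heat.tsv` (per-residue
values), `matrix.tsv` (sparse dependence triplets) and, per `--frame`, a PDB
whose B-factor column carries the rescaled heat for visualization.

Every output directory contains `params.log`, a flat key=value record of the
run that can be replayed with `--config params.log`. All outputs are
deterministic for fixed inputs and seed.

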