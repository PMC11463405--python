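# opsindiff

Comparative structural analysis of chromophore binding pockets in visual
pigments, from molecular-dynamics trajectories.

## The scientific problem

Visual pigments pair an opsin protein with a retinal chromophore bound
through a protonated Schiff base (PSB, the N⁺ linkage to a lysine).  Two
closely related pigments — for example the blue-shifted and green-shifted
green-cone (Rh2) paralogs of zebrafish — can differ in peak absorption
(λmax) by tens of nanometres although their sequences are ~83% identical.
The structural explanation lives in the binding pocket: which residues sit
near the Schiff-base nitrogen and the β-ionone ring, how large and how
hydrated the pocket is, how twisted the polyene chain is, and how stable
the hydrogen-bond network around the counterion (GLU113-type residues) and
the secondary tuning sites (122, 181) remains over the trajectory.

`opsindiff` turns that comparison into a tested, reusable pipeline.  Given
two matched trajectories (same residue numbering, one chromophore each) it
computes:

- **Global fluctuation** — Cα RMSD(t) after Kabsch superposition, and
  per-residue RMSF_i = √⟨|xᵢ(t) − ⟨xᵢ⟩|²⟩.
- **Pocket profile** — lining residues within a distance cutoff of the
  chromophore (the classic 27-residue / 4.5 Å convention for bovine
  rhodopsin), a POVME-style grid pocket volume V(t), and water counts near
  the chromophore.
- **Differential distance screen** — for every residue whose Cα is within
  8 Å of the chromophore, the per-frame distance from that Cα to the
  Schiff-base N⁺ and to the β-ionone ring centroid; the between-system
  difference Δ = ⟨d⟩_B − ⟨d⟩_A is tested with a block-averaged Welch t-test
  (frames are autocorrelated), Benjamini–Hochberg corrected, and gated by a
  0.5 Å effect floor before a residue is called *closer* or *farther*.
- **Chromophore internal coordinates** — Rg(t), per-atom RMSF, named
  torsions (Schiff-base twist CD-CE-N⁺-C15, ring–chain torsions
  C7-C6-C1-C16 and C5-C6-C7-C8) and angles, with circular histograms and a
  von-Mises-KDE monomodal/bimodal classifier.
- **Hydrogen-bond networks** — geometric detection (d(D,A) ≤ 3.5 Å,
  ∠D–H···A ≥ 150°), per-pair occupancy (fraction of frames), and
  water-mediated bridges (both water H-bonds in the same frame).
- **Helix geometry** — centre-of-mass distances between helices and a
  half-split principal-axis bend angle.

Because real opsin trajectories are rarely shareable, the package ships a
first-class synthetic generator (`opsindiff.synthetic`): a cage of minimal
polar residues around a retinal-like chromophore, with *programmed* radial
displacements, H-bond occupancies, torsion mixtures, a pocket-breathing
mode and Gaussian noise.  Every statistic the pipeline reports is validated
by recovering those programmed values.

## Worked example

```bash
$ opsindiff generate --out demo --seed 1 --n-frames 2000
wrote synthetic experiment to demo
$ opsindiff compare --config demo/comparison.yaml
summary written to demo/comparison/summary.json
screen: 2 shifted site(s): ['17', '3']
```

The generator programmed a +1.0 Å radial displacement at cage sites 3 and
17 in system B, occupancy tiers 0.99/0.80/0.18 for three hydrogen bonds, a
0.5-occupancy water bridge, and a bimodal C7-C6-C1-C16 torsion in system B
only.  The summary shows the screen recovered exactly the displaced sites
(both *farther* from N⁺ and from the ring), and the modality calls:

```json
"screen":      {"labelled_sites": {"3":  {"N_plus": "farther", "ionone_ring": "farther"},
                                   "17": {"N_plus": "farther", "ionone_ring": "farther"}},
                "n_qualifying_sites": 7}
"chromophore": {"A": {"modality": {"SB_twist": "monomodal", "ring_chain_1": "monomodal",
                                   "ring_chain_2": "monomodal"}, "rg_mean_A": 5.12172},
                "B": {"modality": {"SB_twist": "monomodal", "ring_chain_1": "bimodal",
                                   "ring_chain_2": "monomodal"}, "rg_mean_A": 5.161347}}
```

Per-section CSV tables (distance screen, occupancy tables, volume and Rg
series, …) land next to `summary.json`; re-running the same config
reproduces the summary byte for byte.

The same machinery works on real data: point `comparison.yaml` at your own
topology PDB and multi-model PDB trajectories, map the chromophore atom
names through the `chromophore:` block, and give the tuning-site numbers
(e.g. 122/181) in `site_map:`.

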