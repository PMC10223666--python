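# vesitraj

Trajectory analysis for self-assembled fatty-acid vesicles — the kind of
single-chain amphiphile compartment (e.g. decanoic acid, C10) studied as a
protocell membrane model.  Given a multi-frame trajectory of an assembled
vesicle, the package computes:

- **Vesicle geometry** from headgroup radii of gyration: per-leaflet shells
  from the carboxyl oxygens (O1/O2), with bilayer thickness
  `t = Rg_outer − Rg_inner` and vesicle radius (outer-shell convention).
- **Leaflet assignment** by molecular orientation — the headgroup→terminal-carbon
  vector against the outward radial — which stays well-defined during
  flip-flop transits, plus the inner-leaflet fraction statistic.
- **Flip-flop counting** with dwell-time hysteresis over the per-frame label
  series.
- **Diffusion** from the all-origin mean squared displacement
  `M(τ) = ⟨|r(t+τ) − r(t)|²⟩` and the Einstein relation `D = M(τ)/2Eτ`
  (`E` = dimensionality), with the anomalous exponent `α` fitted from
  `log M` vs `log τ`; when `|α − 1|` exceeds a threshold the regime is
  flagged anomalous and no `D` is reported.
- **Solvent-accessible surface area** (Shrake–Rupley, quasi-uniform sphere
  lattice, Bondi-style radii, 1.4 Å probe).
- **Chain order parameters** `S = ⟨3cos²θ − 1⟩/2` per tail carbon, measured
  against each monomer's own outward radial normal so the vesicle curvature
  drops out; the C–H direction is reconstructed from heavy atoms.
- **2-D headgroup density maps** on an equal-area (cos θ, φ) grid, and a
  **peptide–amphiphile radial distribution function**.
- **Helix tilt**: angle between the first→last Cα vector of an embedded
  peptide and the local bilayer patch normal (amphiphiles within 8 Å),
  classified as inserted C→N (≈0°), surface (≈90°), or inserted N→C (≈180°).

Because self-assembly trajectories of this kind are rarely deposited, the
package ships a first-class synthetic generator (`vesitraj.synthetic`): a
two-leaflet spherical vesicle with planted shell radii and leaflet counts,
gel (all-trans) or fluid (random-dihedral) tails, fractional-Brownian monomer
motion with a planted `D` and `α`, scripted flip-flop transits, interior
water, and an ideal α-helix at an exact planted tilt — all recorded in a
ground-truth sidecar so every estimator is validated by parameter recovery.

## Worked example

Generate a vesicle with the reference composition (1000 monomers, 21% in the
inner leaflet, 3.5 nm outer shell), a small Brownian drift, and a helix lying
on the bilayer surface, then analyze it:

```bash
vesitraj generate --preset DA-25 --n-frames 60 --d-true 0.02 \
    --peptide-tilt 90 --seed 5 --out fix/da25
cat > cfg.yaml <<EOF
input:
  trajectory: fix/da25.pdb
  topology: fix/da25.topology.yaml
label: DA-25-demo
seed: 5
output_dir: outdir
EOF
vesitraj analyze cfg.yaml
```

prints the summary row

```
{
 "label": "DA-25-demo",
 "radius_nm": "3.51",
 "thickness_nm": "1.49",
 "inner_leaflet_pct": "21.0",
 "diffusion_nm2_ns": "0.02",
 "anomalous": "no",
 "sasa_nm2": "636",
 "flip_flops": "0",
 "tilt_mean_deg": "88.8"
}
```

— the planted radius (3.5 nm), thickness (1.5 nm), inner-leaflet fraction
(21%), diffusion coefficient (0.02 nm²/ns) and tilt (90°) are all recovered;
no flip-flops were planted and none are reported.  Per-analysis artifacts
(geometry.csv, msd.csv, flip_flops.csv, order_parameters.csv,
density_map.txt, tilt.csv, manifest.json, ...) land in `outdir/`.

The same can be done from Python; the numbered drivers under `analysis/`
(01 generate fixtures → 06 merged summary report) run the full story over a
temperature-like series of gel, ripple-like, and fluid compositions and write
their tables under `results/tables/`.

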