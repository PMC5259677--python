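# strandroller

Detection of β-strand central traces (**β-traces**) in β-barrel regions of
medium-resolution (5–10 Å) cryo-EM density maps.

At these resolutions α-helices are visible as cylinders, but the 4.5–5 Å
spacing between neighbouring β-strands is *not* resolved: a β-barrel appears
as a single tube of density with no internal strand separation. `strandroller`
recovers the likely strand positions anyway, by exploiting two conserved
geometric properties of β-barrels: the strand tilt angle α relative to the
barrel axis lies in a narrow range (30°–60°), and the hydrogen-bond
constrained interstrand spacing is d ≈ 4.8 Å.

## Method

Given a segmented β-barrel density map, the pipeline is:

1. **Axis identification** — exhaustive search over a hemisphere of candidate
   directions (5° grid, 1° local refinement). For each candidate the occupied
   voxels are projected along it and fit with a least-squares ellipse
   x²/a² + y²/b² = 1; the direction minimising the summed squared radial
   residuals is the barrel axis, and the map is rotated so it aligns with +z.
2. **Discrete surface model** — per z-cross-section, an ellipse is fit to the
   slice (refined onto the density ridge), and in each azimuthal bin the
   occupied voxel closest to the ellipse is selected as a surface point. The
   surface therefore follows the density where the barrel morphs away from an
   ideal elliptical cylinder, especially at its two ends.
3. **Recursive trace generation** — an initial β-trace is laid on the surface
   keeping angle α with the axis; each further trace starts a horizontal arc
   distance

       h = d / cos α,   d = 4.8 Å

   around the mid-height cross-section from the previous one, until the set
   closes around the barrel. Sampling α every 5° in 35°–55° with three
   translation phases per tilt yields **fifteen candidate trace sets**, which
   are rotated back into the original map frame.
4. **Evaluation** (when an atomic structure is available) — the observed
   β-trace of a strand interpolates the geometric centers of every three
   consecutive Cα atoms plus the two end Cαs. Detected and observed sets are
   matched one-to-one by optimal assignment on the symmetric two-way curve
   distance D_k (mean point-to-polyline projection distance, averaged over
   both directions); the overall distance D is the mean over matched pairs,
   and a residue counts as detected when its Cα lies within 2.5 Å (strictly)
   of the matched trace. The best of the fifteen sets is the one minimising D.

A synthetic-data module generates closed ideal barrels (circular or
elliptical, optionally with ragged strand ends) with full ground truth and
renders them to density at a stated resolution (Gaussian kernel with
σ = resolution/(π√2), the common simulation convention), so that every stage
is testable without downloading any structures.

## Worked example

Simulate an 8-strand barrel at 45° tilt, render it at 10 Å resolution and
1 Å/voxel, then detect and score the traces against the generating structure:

```sh
strandroller simulate --n-strands 8 --tilt 45 -o demo
strandroller evaluate demo.mrc demo.pdb --sheet-id BRL -o demo_eval
```

which prints

```
INFO strandroller: wrote demo.mrc (35x35x39 voxels)
INFO strandroller: best of 15 sets: tilt 45°, D = 0.50 Å, strands 8/8, AA 80/80
```

i.e. the best of the fifteen candidate sets used the true tilt (45°), found
all 8 strands, placed the traces an average two-way distance of 0.50 Å from
the observed ones, and all 80 Cα atoms lie within the 2.5 Å coverage cutoff.
Per-set reports (`report.json`, `report.csv`) and the best trace set as a
Cα-pseudoatom PDB are written to `demo_eval/`.

The library surface mirrors the CLI: `strandroller.detect(density_map)`
returns the axis, surface model and the fifteen trace sets, and
`strandroller.select_best_set(...)` scores them against observed traces.

## Limitations

Segmentation of the barrel region out of a whole cryo-EM map is out of
scope — the input is assumed to be an isolated β-barrel density. Traces span
the full axial extent of the surface model: per-strand length trimming and
strand stagger (shear) are not modelled, and a single tilt angle is used per
candidate set although real barrels can vary by ±15° between strands. See
`docs/methods.md` for the model assumptions and numerical choices in detail.
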