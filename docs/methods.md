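# Methods

This note records the models, conventions and open design choices behind
each analysis stage, what the synthetic-data generator does and does not
emulate, and the numerical settings that matter.

## Trajectory model and I/O

A trajectory is an ordered stack of frames sharing one atom identity list
(serial, name, element, residue, chain). Identity constancy is enforced
at construction; a multi-model PDB whose second MODEL drops or renames an
atom is rejected with the offending frame named, because every downstream
per-atom statistic assumes positional correspondence across frames.

Residue numbering is kept exactly as in the input (1-based, so the GCP4
pocket mutation site is residue Ser623); nothing is renumbered. Chains
come from the PDB chain field; chain-less files are rejected rather than
guessed. PDB coordinates carry three decimals, so all round-trip
assertions use a 1e-3 Å tolerance. XYZ frame stacks carry no chain or
residue identity at all, so reading them requires a template frame
supplying the identity; element symbols are cross-checked against it.

PDBQT pose files follow the multi-model dialect with a per-model
`REMARK VINA RESULT` line whose first numeric field is the docking score
in kcal/mol; a model without the remark is a parse error. Ligand records
often leave the chain column blank; blank pose chains are mapped to `L`.

## Superposition and RMSD series

Rigid superposition is the least-squares (Kabsch) fit with reflections
excluded, delegated to `scipy.spatial.transform.Rotation.align_vectors`.
Selections of fewer than three atoms, or collinear ones (second singular
value of the centered coordinates below 1e-8 of the first), are rejected
as geometry errors rather than resolved by an arbitrary tie-break.

The RMSD-vs-time table corrects for global motion the standard way: each
frame is superposed onto the reference using *all* atoms, then each named
group's RMSD is read off in that single global fit without per-group
re-fitting. Group traces therefore report internal rearrangement relative
to the whole complex, not the group's own best fit.

## Persistent contacts

Two atoms on different chains are in contact when their Euclidean
distance is **≤ 3.0 Å** (inclusive). A contact's identity is the *atom
pair*; its persistence is the fraction of analysed frames in which it is
in contact, and it is reported when that fraction is **strictly greater
than 0.90** — presence in exactly 90% of frames does not qualify. Both
boundary conventions are tested explicitly. The threshold source text
("below a specified threshold", "exceeded a predetermined threshold")
does not fix the behaviour at exactly 3.000 Å or exactly 0.900, so the
inclusive-distance / strict-persistence reading is documented here as the
package's convention.

All atoms, hydrogens included, participate by default (the systems of
interest are all-atom simulations); `heavy_atoms_only` restricts the
search. Restricting persistent contacts to polar (N/O/H) pairs with
`donor_acceptor_subset` yields the candidate pool a hydrogen-bond search
would draw from; since hydrogen bonds add angular criteria on top of
distance, a true H-bond list is a subset of the distance-based one.

The default analysis window drops the leading 30% of frames as
equilibration — expressed as a fraction so it scales from a 10 ns
production run (≈3 ns equilibration) down to short synthetic
trajectories — and is overridable, since whether a persistence count
should include the equilibration phase is a per-study decision.

Residue-level histograms count a residue pair as present in a frame when
*any* of its atom pairs is in contact there, so the residue fraction is
the union fraction and never falls below any member atom pair's fraction.
Interface lists are the unique residues per chain, sorted by number and
formatted as capitalised three-letter code plus number (`Glu367`).

## Frame clustering

Frames are clustered greedily under superposition RMSD: visiting frames
in trajectory order, a frame joins the first cluster whose centroid is
within the cutoff (default 1.5 Å), else seeds a new cluster; centroids
are running means of member coordinates in the cluster's own reference
frame, and dispersion is the mean member-to-centroid RMSD after the final
centroid is fixed. Published workflows often use kclust-style tools whose
exact parameters are rarely stated; this greedy scheme is a documented
stand-in that coincides with them on the clean single-cluster case (one
family of frames, dispersion = mean RMSD to the centroid).

## Fragment filtering

All range bounds are **inclusive**: "from 200 to 500 Da" is read as
[200, 500], and the boundary cases (MW 200/500, logP 2, MR 40/130,
20/70 atoms, PSA 200) are tested. The atom-count range refers to the
total atom count including hydrogens; the heavy-atom count (HAC) is
carried as its own descriptor. Descriptors are inputs: the module filters
vendor-supplied property tables (CSV, or SDF property tags via RDKit) and
deliberately does not recompute logP/PSA, which would introduce a
predictor dependence into what is otherwise exact range arithmetic.

One inconsistency in the source material is surfaced rather than
reconciled: the stated filter caps logP at 2, while the filtered
library's reported average logP is 3. Both cannot hold; the package
implements the stated ranges as printed, and any table whose mean logP
exceeds the cap simply cannot have passed this filter.

Summary histograms use 10 equal-width bins over each property's observed
range (recorded in the output), matching how screening-library property
distributions are conventionally displayed.

## Docking post-processing

Pose–pose RMSD is computed **without superposition**: poses from one
docking run share the receptor coordinate frame, and superposing them
would collapse genuinely distinct sub-sites. Equivalent-atom permutations
(molecular symmetry) are ignored; for symmetric ligands this can inflate
RMSD and split clusters, a known limitation.

Clustering is greedy and energy-ordered: poses are visited by ascending
score, each joins the first cluster whose seed is within the cutoff
(default 2.0 Å — a docking-community convention, since published
workflows rarely print their cutoff), else seeds a cluster. Because seeds
are visited best-first, each cluster's representative is automatically
its lowest-energy member. The screen's hit is the representative of the
largest cluster, size ties broken by lower energy.

Compound ranking resolves "maximum number of conformations and minimum
energy" as a lexicographic order: largest cluster size descending, then
best energy ascending, then compound id — a deterministic total order
invariant under input permutation.

Pocket membership: a receptor residue belongs to the binding-site
footprint when any of its atoms is within the cutoff (default 4.0 Å,
configurable — pocket definitions in the literature rarely print their
cutoff) of any atom of any pose. Footprints are reported per chain as
sorted inclusive ranges ("515–536, 617–632"). Grid boxes carry
floor(size/spacing)+1 points per axis.

## DSF fitting

The transition model is the four-parameter Boltzmann sigmoid
F(T) = F_min + (F_max − F_min)/(1 + exp((Tm − T)/a)), evaluated through
the logistic `expit` for overflow safety. SYPRO-Orange curves decay after
the unfolding peak as dye is released, so the fit window runs from the
scan start to the temperature of maximum fluorescence (smoothed with a
5-point moving average so a noise spike cannot truncate the window); the
window is recorded on every fit.

Initialisation is deterministic: Tm₀ at the maximum first difference of
the smoothed signal, baselines at the window extrema, a₀ = 2 °C.
Convergence tolerance is 1e-10 (ftol/xtol/gtol) in
`scipy.optimize.curve_fit`. A fit is reported unconverged — never
dropped — when the optimizer fails or the result is degenerate
(F_max ≤ F_min, a ≤ 0, Tm outside the window, or a flat curve with no
transition).

Replicate wells are fitted independently; a condition's Tm is the mean
over converged replicate fits with its standard error. ΔTm is the
condition Tm minus the reference (typically the 1:1 protein complex).
Classification: ΔTm ≥ +threshold → stabilizer, ≤ −threshold →
destabilizer, else no effect. The default threshold is 2 °C (the
"best hit" tier); a 1 °C tier is conventional for "any effect"
screening, and the threshold is an explicit parameter because no single
value suits every assay's noise floor. Fitted Tm is invariant under
affine rescaling of fluorescence (gain/offset), which is tested.

## Synthetic data: what it shows and what it does not

The generators plant *answers*, not physics:

- **Trajectories** place each planted contact on a dedicated, spatially
  isolated atom pair, in contact (at the specified distance) in exactly
  round(fraction × n_frames) frames chosen by seeded permutation — so
  persistence is insensitive to window placement — and ≥ 6 Å apart
  otherwise. Bulk atoms get optional Gaussian jitter; optional global
  rigid motion exercises superposition correction without changing any
  interatomic distance. Chains use minimal 3-atom residues to keep
  all-pairs oracles O(n²)-cheap. Nothing force-field-like is simulated:
  passing tests demonstrate the *counting and geometry* are right, not
  that any particular complex is stable.
- **Pose sets** are rigid copies of a 5-atom ligand translated within
  ±jitter around family centers separated far enough that families cannot
  merge at the intended cutoff (validated: separation > 2√3·jitter +
  cutoff); energies increase by 0.05 kcal/mol within a family.
- **Property tables** draw in-range records uniformly inside every filter
  range and out-of-range records with 1–2 planted violations each
  (recorded per record).
- **Plates** sample the standard scan — start-inclusive readings every
  0.3 °C from 20 °C up to (not including) 89.9 °C, i.e. 233 points —
  with planted (F_min, F_max, Tm, a), optional linear post-peak decay
  beginning at Tm + 8a (to exercise window truncation), and i.i.d.
  Gaussian noise. Default planted conditions use F_min 1000 / F_max
  10000 AU, a = 2 °C and triplicates; the screen-validation plates plant
  the reference melting temperatures 33 °C (γ-tubulin), 42 °C (GCP4) and
  45 °C (complex), and a 20-ligand screen with a 2-stabilizer /
  8-destabilizer / 10-inert split. Real plates add well-to-well gain
  variation, drift and occasional aggregation artefacts that these curves
  do not contain.

All generators are deterministic per (spec, seed); identical seeds give
byte-identical output files.

## Problem sizes

The test suite and acceptance script run at desk scale by design:
trajectories of 60–200 frames with ≤ 4 planted contacts and ≤ 100-atom
frames for brute-force comparison; 20-pose docking sets; a
50,000-compound library with 500 planted passes for the filtering run
(mirroring a 50,000 → 500 screening funnel); 100-seed noise replicates
per planted Tm for fit-recovery statistics. These sizes make every
brute-force oracle exact and fast while leaving the algorithms identical
to what full-scale inputs would use.

## Known limitations

- No symmetry-corrected pose RMSD; no angular hydrogen-bond criteria.
- The frame-clustering algorithm is a documented greedy stand-in, not a
  reimplementation of any specific published clustering tool.
- Docking energies, mutant-pocket energetics and binding-site prediction
  are upstream of this package (pose files and descriptors are inputs).
- No thermodynamic interpretation of thermal shifts (no ΔG/Kd from ΔTm).
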