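# gtusc

Analysis toolkit for structure-based fragment screening against the
interface of the γ-tubulin small complex — specifically the contact
surface between GCP4 (γ-tubulin complex protein 4) and γ-tubulin, a
candidate target for inhibiting microtubule nucleation.

The package covers the four computational stages of such a screen, each
usable on its own and each testable against synthetic data with known
ground truth:

1. **Persistent-contact analysis of MD trajectories** (`gtusc.contacts`).
   For every intermolecular atom pair, the fraction of analysed frames
   with distance ≤ 3 Å is measured; pairs whose fraction strictly exceeds
   90% are *persistent contacts*. Built on Kabsch superposition (proper
   rotations only), with superposition-corrected RMSD time series,
   residue-pair contact histograms, interface residue lists and greedy
   centroid frame clustering.
2. **Fragment-library filtering** (`gtusc.fragments`). Lipinski-style
   inclusive range filters on vendor descriptors: MW 200–500 Da,
   logP −5…2, molar refractivity 40–130 m³·mol⁻¹, 20–70 atoms,
   PSA ≤ 200 Å²; plus per-property means and histograms.
3. **Docking post-processing** (`gtusc.dockrank`). Greedy energy-ordered
   RMSD clustering of poses (no superposition — poses share the receptor
   frame), representative = lowest-energy member of the largest cluster,
   compound ranking by (largest cluster size ↓, best energy ↑), pocket
   residue enumeration by distance cutoff, and grid-box arithmetic.
4. **DSF melt-curve analysis** (`gtusc.thermofluor`). Boltzmann-sigmoid
   fits F(T) = F_min + (F_max − F_min)/(1 + exp((Tm − T)/a)) over the
   pre-peak window, replicate averaging, thermal shifts
   ΔTm = Tm(condition) − Tm(reference), and stabilizer / destabilizer /
   no-effect classification.

`gtusc.synthgen` generates every input format the pipeline reads
(multi-model PDB trajectories, multi-model PDBQT pose files with VINA
RESULT energies, property CSVs, plate CSVs) with machine-readable ground
truth; `gtusc.structio` does the parsing and writing.

## Worked example

Persistence screening of a synthetic trajectory with four planted contact
pairs (`examples/contact_persistence.py`):

```text
planted fractions: [1.0, 0.95, 0.6, 0.1]

persistent contacts (fraction > 0.90): 2
  B/Ala1/N         -- D/Ala1/N         present 200/200 frames (1.00)
  B/Gly2/N         -- D/Gly2/N         present 190/200 frames (0.95)

interface residues per chain:
  chain B: Ala1, Gly2
  chain D: Ala1, Gly2
```

Only the pairs in contact in more than 90% of frames survive; the 0.60
and 0.10 pairs are transient and are dropped. The interface lists are the
unique residues contributed by the surviving contacts, per chain.

A DSF screen (`examples/fit_melt_curves.py`) prints per-condition fitted
melting temperatures and classifications:

```text
    condition  n_replicates  n_converged    Tm  Tm_se  delta_Tm classification
      complex             3            3 45.01   0.01      0.00      reference
complex+NM156             3            3 47.60   0.01      2.59     stabilizer
complex+NM372             3            3 42.41   0.01     -2.60   destabilizer
 complex+dmso             3            3 44.89   0.01     -0.12      no_effect
```

Tm is the sigmoid midpoint averaged over triplicate wells; a ligand
shifting Tm of the complex by at least 2 °C in either direction is a hit.

The other examples (`rank_docking_poses.py`, `filter_fragment_library.py`)
cover pose clustering/ranking and library filtering. A thin CLI mirrors
the library (`gtusc io|contacts|fragments|dock|dsf|synth --help`).

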