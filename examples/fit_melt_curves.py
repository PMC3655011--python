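"""Fit DSF melt curves and classify thermal shifts.

Generates a triplicate plate for the two proteins, their complex and four
ligand conditions, fits every well with the Boltzmann sigmoid, and
classifies each ligand by its shift against the complex.
"""

from gtusc import synthgen as sg
from gtusc.thermofluor import fit_plate

spec = sg.PlateSpec(
    conditions=(
        sg.ConditionSpec("gamma-tubulin", tm_C=33.0),
        sg.ConditionSpec("GCP4", tm_C=42.0),
        sg.ConditionSpec("complex", tm_C=45.0),
        sg.ConditionSpec("complex+NM372", tm_C=42.4),  # destabilizer
        sg.ConditionSpec("complex+NM156", tm_C=47.6),  # stabilizer
        sg.ConditionSpec("complex+inert", tm_C=45.2),  # no effect
        sg.ConditionSpec("complex+dmso", tm_C=44.9),   # no effect
    ),
    noise_sigma_AU=90.0,       # ~1% of the 9000 AU transition amplitude
    decay_rate_AU_per_C=80.0,  # post-peak dye-release decay
    seed=2013,
)
plate, truth = sg.gen_plate(spec)
table = fit_plate(plate, reference="complex", effect_threshold_C=2.0)
print(table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))

# Tm is the sigmoid midpoint of each well, averaged over triplicates; the
# complex melts ~12 °C above gamma-tubulin alone (complex formation
# stabilizes both partners), and ligands shifting Tm by at least 2 °C in
# either direction are reported as stabilizer/destabilizer hits.
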