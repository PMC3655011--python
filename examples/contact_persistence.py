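"""Persistent-contact analysis of a synthetic two-chain trajectory.

Generates a 200-frame trajectory with four atom pairs planted in contact
for known fractions of frames, then runs the persistence screen at the
standard 3 Å / 90% settings.
"""

from gtusc import synthgen as sg
from gtusc.contacts import interface_residues, persistent_contacts

spec = sg.TrajectorySpec(
    n_frames=200,
    chains=(sg.ChainSpec("B", 4), sg.ChainSpec("D", 4)),
    planted_contacts=tuple(sg.PlantedContact(f)
                           for f in (1.0, 0.95, 0.60, 0.10)),
    jitter_sigma_A=0.1,
    global_motion=True,
    seed=42,
)
traj, truth = sg.gen_trajectory(spec)
print("planted fractions:", list(truth.contacts["realized_fraction"]))

found = persistent_contacts(traj, ("B", "D"), threshold_A=3.0,
                            persistence=0.90, window=(0, 200))
print(f"\npersistent contacts (fraction > 0.90): {len(found)}")
for c in found:
    print(f"  {c.atom_i.label():<16s} -- {c.atom_j.label():<16s} "
          f"present {c.n_frames_present}/{c.n_frames_total} frames "
          f"({c.persistence_fraction:.2f})")

print("\ninterface residues per chain:")
for chain, names in interface_residues(found).items():
    print(f"  chain {chain}: {', '.join(names)}")

# Only the pairs planted above 90% survive the persistence screen; the
# 0.60 and 0.10 pairs are transient contacts and are correctly dropped.
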