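"""Generate, store and replay a phase-space file for an HDR Ir-192 source.

A phase-space (PHSP) file records every photon crossing the seed's outer
surface (energy, position, direction, weight) so later simulations can use
the seed as a source without re-modelling its internals.  The script prints
the escape fraction (capsule self-absorption), verifies the byte-exact
round trip, and replays the file at a rotated pose.
"""

import os
import tempfile

import numpy as np

from brachymc import (Pose, build_seed, generate_phsp, read_phsp,
                      replay_source, write_phsp)

seed = build_seed("NucletronMHDRv1")
f = generate_phsp(seed, n_records=50_000, rng=7)
info = f.info()
print(f"seed {info['seed_id']} ({info['nuclide']}): "
      f"{info['n_records']} records from {info['n_primary']} decays")
print(f"escape fraction {info['escape_fraction']:.3f} "
      "(photons surviving core + capsule self-absorption)")
print(f"mean escaping energy {info['mean_energy_keV']:.1f} keV "
      "(the bare Ir-192 spectrum averages ~355 keV; capsule hardening and "
      "core scatter shift it)")

with tempfile.TemporaryDirectory() as d:
    path = os.path.join(d, "mhdr_v1.phsp")
    write_phsp(f, path)
    back = read_phsp(path)
    print("round trip bit-exact:", np.array_equal(back.records, f.records))

pose = Pose(translation=(20.0, 0.0, 0.0), axis=(1, 0, 0), angle_deg=90.0)
e, pos, dirs, w, hist = replay_source(f, pose, 10_000,
                                      np.random.default_rng(0))
print(f"replayed 10^4 particles at a rotated pose: "
      f"mean position {pos.mean(axis=0).round(2)} mm (centred on the "
      f"pose translation), mean energy {e.mean():.1f} keV")
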