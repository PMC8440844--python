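"""Accelerometer inverse filtering: forward-model a neck-surface
acceleration from a glottal flow, invert it, and calibrate the
subject-specific parameters by particle swarm optimization.
"""

import numpy as np

from voxphys.ibif import (
    IBIFParams,
    band_rms_error,
    calibrate_pso,
    default_bounds,
    forward_acc,
    ibif_inverse,
)
from voxphys.pipeline import glottal_pulse_train

fs = 8192.0
nominal = IBIFParams(skin_mass=2.0, skin_stiffness=1.3e6, skin_damping=600.0,
                     trachea_length=0.115, sensor_depth=0.05)

# a 'subject' whose trachea/skin differ from nominal
subject = IBIFParams(skin_mass=2.3, skin_stiffness=1.1e6, skin_damping=700.0,
                     trachea_length=0.12, sensor_depth=0.055)

ug = glottal_pulse_train(130.0, fs, 0.3) * 1e-6          # m^3/s
acc = forward_acc(ug, subject, fs)                        # what the sensor sees

sl = slice(820, -820)  # interior, clear of finite-window edges
err_nominal = band_rms_error(ibif_inverse(acc, nominal, fs)[sl], ug[sl] * 1e6, fs)
print(f"inversion with nominal parameters: {100 * err_nominal:.1f}% band RMS error")

best, cost = calibrate_pso(acc, ug * 1e6, fs, default_bounds(nominal),
                           seed=0, swarm_size=24, iters=40, nominal=nominal)
print(f"after PSO calibration: {100 * cost:.2f}% waveform error")
print(f"recovered trachea length {best.trachea_length * 100:.2f} cm "
      f"(truth {subject.trachea_length * 100:.2f} cm)")
print(f"recovered sensor depth  {best.sensor_depth * 100:.2f} cm "
      f"(truth {subject.sensor_depth * 100:.2f} cm)")
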