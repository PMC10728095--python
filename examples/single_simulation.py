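"""Simulate one tumor under an active vs a blocked PD-1/PD-L1 checkpoint.

A 1 mm³ inoculum (50% high-antigen, 50% low-antigen cells, no pre-existing
T-cell infiltrate) is integrated for 150 days at the baseline mouse
parameterization. Printed volumes are in mm³; the low-antigen fraction
M/(N+M) tracks how killing reshapes tumor composition.
"""

from ctldyn import (CheckpointMode, ParameterSet, default_initial_state,
                    integrate)

params = ParameterSet.baseline()
init = default_initial_state(params)  # 1 mm³, 50/50, T(0) = 0

for mode in CheckpointMode:
    tr = integrate(params, init, mode, t_end=150.0)
    print(f"checkpoint {mode.value}:")
    for day in (25.0, 150.0):
        print(f"  day {day:>5.0f}: volume = {tr.volume_at(day):8.1f} mm3, "
              f"low-antigen fraction = {tr.low_fraction_at(day):.2f}, "
              f"outcome = {tr.label_at(day).value}")

# With the checkpoint active, killing is suppressed and the tumor grows to
# carrying capacity (5000 mm³). Blockade restores killing: the tumor is ~75%
# smaller on day 25, but because high-antigen cells die faster (p1 > p2) the
# survivors are low-antigen, and that resistant clone regrows by day 150.
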