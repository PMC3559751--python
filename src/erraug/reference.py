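"""Reference group-level results for the error-augmentation paradigm.

Published group summaries (mean +/- SD over four subjects per group) of
the exponential-fit parameters for 30 degree visuomotor-rotation learning
under the four feedback conditions.  These serve as generating parameters
for parameter-recovery benchmarks and as inputs to the worked effect-size
and percent-reduction examples; they are inputs to the analysis, not
outputs of it.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "GroupReference",
    "GROUP_SUMMARY",
    "AMOUNT_EFFECT",
    "RATE_EFFECT",
    "CATCH_RESIDUAL_RMS_M",
]


@dataclass(frozen=True)
class GroupReference:
    """Training-phase summary for one group (means +/- SD, n = 4)."""

    group: str
    initial_error_m: float
    initial_error_sd_m: float
    amount_A_m: float
    amount_A_sd_m: float
    steady_C_m: float
    steady_C_sd_m: float
    time_constant_B: float  # movements
    time_constant_B_sd: float


#: Group summary table: initial error, learning amount A, steady state C,
#: time constant B, for the control, gain-2, offset and gain-3.1 groups.
GROUP_SUMMARY: dict[str, GroupReference] = {
    "control": GroupReference("control", 0.029, 0.002, 0.016, 0.002, 0.007, 0.001, 50.9, 10.60),
    "x2": GroupReference("x2", 0.031, 0.002, 0.014, 0.004, 0.010, 0.002, 33.4, 7.66),
    "offset": GroupReference("offset", 0.032, 0.002, 0.022, 0.003, 0.011, 0.002, 38.1, 4.74),
    "x3p1": GroupReference("x3p1", 0.030, 0.001, 0.016, 0.002, 0.011, 0.001, 51.9, 14.24),
}

#: Narrative-text group means +/- SD used for the effect-size worked
#: examples (reported at higher precision than the summary table):
#: learning amount, offset vs control, in mm; time constant, gain-2 vs
#: control, in movements.
AMOUNT_EFFECT = {"offset": (22.7, 3.6), "control": (17.5, 1.3)}  # mm
RATE_EFFECT = {"x2": (29.1, 10.3), "control": (44.8, 8.9)}  # movements

#: Average RMS residual of the exponential fits to catch-trial series.
CATCH_RESIDUAL_RMS_M = 0.94e-3
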