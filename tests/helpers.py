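"""Shared fixtures-as-data for the kernel checks."""

from thermolba.lba import LBACellParams

#: parameter sets spanning the prior ranges, reused by kernel checks
KERNEL_PARAM_SETS = [
    LBACellParams(A=0.5, B=0.5, v_correct=3.0, delta_v=2.0, s_error=1.0, t0=0.2),
    LBACellParams(A=0.2, B=1.5, v_correct=1.0, delta_v=0.5, s_error=0.5, t0=0.1),
    LBACellParams(A=1.0, B=0.3, v_correct=4.0, delta_v=1.0, s_error=1.5, t0=0.3),
    LBACellParams(A=0.05, B=2.0, v_correct=2.0, delta_v=0.0, s_error=1.0, t0=0.05),
    LBACellParams(A=0.8, B=0.8, v_correct=1.5, delta_v=1.5, s_error=0.3, t0=0.4),
]
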