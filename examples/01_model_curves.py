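"""Evaluate the retinal-function model at its key operating points.

The model predicts relative ERG b-wave amplitude (% of baseline) from
relative ocular blood flow and IOP: flow sets oxygen consumption through
the exponential OER-flow law, and IOP above the mechanical threshold
subtracts a linear stress term.
"""

import numpy as np

from ergflow import TABLE1_PARAMS, erg_model, iopm_from_iop, oer_from_flow

p = TABLE1_PARAMS
print(f"calibrated parameters: a={p.a}, b={p.b}, t={p.t} mmHg, m={p.m} %/mmHg")

print("\nOER vs flow (fold; 1.0 = baseline extraction):")
for flow in (0, 50, 100, 150, 200):
    print(f"  flow {flow:3d}% -> OER {float(oer_from_flow(flow, p)):.3f}")
# OER rises ~4.4-fold as flow vanishes (ischaemic reserve) and falls
# below onefold during hyperperfusion.

print("\nmechanical stress vs IOP (% ERG; 0 until the threshold):")
for iop in (10, 40, 50, 70, 120):
    print(f"  IOP {iop:3d} mmHg -> IOP_M {float(iopm_from_iop(iop, p)):+.1f}%")

print("\npredicted ERG amplitude (% baseline):")
for flow, iop in ((100, 10), (200, 10), (80, 70), (40, 100), (10, 120)):
    erg = float(erg_model(flow, iop, p))
    print(f"  flow {flow:3d}%, IOP {iop:3d} mmHg -> ERG {erg:6.1f}%")
# Baseline (100%, 10 mmHg) returns exactly 100%; hyperperfusion does not
# raise function above baseline; combined low flow + high IOP drives the
# ERG toward zero.
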