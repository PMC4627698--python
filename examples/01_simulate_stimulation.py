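"""Equilibrate the model, stimulate with ligand, and print the readouts.

The model is first run to its unstimulated steady state (downstream outputs
are structurally zero there), then 20 ug/mL of ligand is applied at t = 0
and the trajectory is reported each minute for 30 minutes.
"""

import numpy as np

from bcrsignal import (StimulusProtocol, assemble_model, nominal_parameters,
                       run_to_steady_state, simulate_stimulation)

params = nominal_parameters()
ledger = assemble_model(params, "WT")
baseline = run_to_steady_state(params, "WT", ledger=ledger)
tc = simulate_stimulation(baseline, params,
                          StimulusProtocol(ligand_dose=20.0, scenario="WT"),
                          ledger=ledger)

print("t [min]   Erkp     NFkB    IkB(nd)   DAG")
for i in range(0, 31, 5):
    print(f"{tc.t[i]:5.0f}  {tc.output('Erkp')[i]:8.4f} {tc.output('NFkB')[i]:8.4f}"
          f" {tc.output('IkB_nondegraded')[i]:8.4f} {tc.output('DAG')[i]:8.4f}")

print()
print("Erkp is the sum of singly and doubly phosphorylated Erk; it rises from")
print("its zero baseline to a plateau as the MAPK cascade saturates.  Free")
print("NF-kB climbs as IKK phosphorylates IkB out of the inhibitory complex,")
print("and non-degraded IkB falls correspondingly from its basal level of 1.")
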