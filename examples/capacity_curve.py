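"""Storage capacity and silent-synapse fraction versus the statistics parameter B.

B collapses the four moments of the input/target rate distributions into
one number; alpha_c is the largest number of associations per synapse
that a perceptron with non-negative weights can store with zero error,
and F is the fraction of synapses the optimal solution silences.
"""

import numpy as np

from excitatory_perceptron import capacity_curve

df = capacity_curve(np.array([0.0, 0.5, 1.0, 2.0, 5.0, 10.0]))
print(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(
    "\nAt B = 0 (noiseless targets) half the synapses are silent and the "
    "capacity is 0.5 associations per synapse -- half the unconstrained "
    "value of 1.  Larger B (more variable targets, relative to the input "
    "variability) lowers the capacity and silences more synapses; note "
    "alpha_c + F = 1 in every row."
)
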