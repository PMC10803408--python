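"""Exact redundancy/synergy analytics for the XOR and COPY benchmark gates.

The n-COPY gate (n identical copies of one fair bit) is the maximally
redundant system; the n-XOR gate (n-1 fair bits plus their parity) is the
maximally synergistic one. Their gradients of O-information attain the
tight first-order bounds -(n-2) log|X| and +log|X| exactly, and their
second-order gradients are 0 (COPY) and (2-n) log|X| (XOR): pairs of COPY
variables add no redundancy beyond singles, while pairs of XOR variables
carry an irreducible synergistic contribution that grows linearly with n.
"""

from oigrad import run_gate_demo

for kind in ("copy", "xor"):
    for n in (3, 5):
        run_gate_demo(kind, n, units="bits")
        print()
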