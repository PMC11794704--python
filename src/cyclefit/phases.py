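"""Cell-cycle phase vocabulary shared across the package.

Phases are ordered (G1, S/G2, M, Multinucleated); every state vector,
transition matrix and count table in the package uses this ordering.
Multinucleated is an absorbing state entered on mitotic failure.
"""

from __future__ import annotations

PHASES: tuple[str, ...] = ("G1", "S/G2", "M", "Multinucleated")

G1, SG2, M, MULTI = range(4)

N_PHASES = len(PHASES)

PHASE_INDEX: dict[str, int] = {name: i for i, name in enumerate(PHASES)}
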