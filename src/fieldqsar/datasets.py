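"""Built-in reference data: the FLT3 pteridinone binding-energy table.

Published per-complex binding energies for seven pteridin-7(8H)-one
inhibitors bound to wild-type FMS-like tyrosine kinase-3 (FLT3) plus the most
active compound bound to the D835Y activation-loop mutant: experimental
affinities deduced from IC50 alongside end-state MM-PB/GBSA estimates,
steered-pulling rupture forces (pN), linear-interaction-energy estimates and
alchemical (FEP) estimates, all in kcal/mol except the rupture force.

Correlation analyses of wild-type affinity conventionally exclude the mutant
complex (``MUTANT_COMPLEX_ID``).
"""

from __future__ import annotations

import pandas as pd

from .molio import EnergyTable

MUTANT_COMPLEX_ID = "FLT3_D835Y-C31"

_ROWS = [
    # complex_id,      dg_exp, dg_mmpbsa,  fmax,  dg_lie, dg_fep
    ("FLT3-C01",        -8.98,   -22.70, 221.40, -28.76, -14.83),
    ("FLT3-C03",        -8.24,   -22.62, 441.13, -27.18, -14.64),
    ("FLT3-C06",        -7.26,   -21.71, 391.61, -28.71, -13.68),
    ("FLT3-C17",        -9.29,   -26.84, 428.75, -30.65, -16.77),
    ("FLT3-C22",       -11.38,   -30.83, 475.17, -30.97, -15.04),
    ("FLT3-C28",       -10.25,   -30.97, 441.13, -30.35, -17.61),
    ("FLT3-C31",       -12.15,   -32.15, 537.07, -28.92, -17.87),
    (MUTANT_COMPLEX_ID, -12.00,  -30.54, 453.51, -28.17, -16.82),
]


def flt3_energy_table() -> EnergyTable:
    """The 8-complex FLT3 binding-energy reference table."""
    df = pd.DataFrame(
        _ROWS, columns=["complex_id", "dg_exp", "dg_mmpbsa", "fmax", "dg_lie", "dg_fep"]
    )
    return EnergyTable(df)


# Published external-validation statistics of the corresponding field-QSAR
# models (CoMFA; CoMSIA steric+hydrophobic), used as worked-example inputs for
# the metric-consistency checks.
COMFA_TEST_RM2 = 0.768
COMFA_TEST_RM2_PRIME = 0.790
COMSIA_TEST_RM2 = 0.758
COMSIA_TEST_RM2_PRIME = 0.785
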