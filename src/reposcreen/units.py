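"""Small pharmacology unit conversions."""

from __future__ import annotations


def ng_per_ml_to_nM(concentration_ng_per_ml: float,
                    molecular_weight_g_per_mol: float) -> float:
    """Convert a mass concentration (ng/mL) to a molar one (nM).

    ng/mL equals ug/L, so dividing by the molecular weight (g/mol) gives
    umol/L and a factor of 1000 converts to nmol/L.  Example: a selinexor
    plasma Cmax of 680 ng/mL at MW 443.31 g/mol is 1533.9 nM.
    """
    if molecular_weight_g_per_mol <= 0:
        raise ValueError("molecular weight must be positive")
    return concentration_ng_per_ml / molecular_weight_g_per_mol * 1e3
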