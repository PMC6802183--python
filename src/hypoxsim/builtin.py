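"""The shipped reconstructed hypoxia / tumor-signaling model.

The model tables under ``hypoxsim/data`` are a compact reconstruction of
the integrated system: a HIF module (constitutive HIF-1α synthesis,
O₂-coupled prolyl-hydroxylase degradation operating near saturation — the
source of the switch-like induction — ARNT binding and HRE-driven mRNA
production) feeding VEGF synthesis in a VEGF/EGF receptor → PI3K/Akt and
SOS/RAF/MEK/ERK signaling module whose phosphorylation steps are
ATP-dependent.  Every row is flagged ``provenance=reconstructed``: rate
constants were chosen to reproduce the qualitative behaviour of the
source models (receptor-proximal seconds-to-minutes kinetics, switch-like
HIF induction, VEGF-driven Akt activation, ATP-limited phosphorylation
under severe hypoxia), not copied from any supplementary table.

Species initial values in the table are the nominal normoxic steady state
of the integrated model, so population sampling is centred on a
self-consistent baseline.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Dict, Tuple

from .network_model import (
    CouplingConfig,
    ReactionNetwork,
    assemble_integrated_model,
    load_model_tables,
)

__all__ = [
    "builtin_tables",
    "load_hif_network",
    "load_tumor_network",
    "builtin_model",
    "RATIO_MAPPING",
    "PUBLISHED_SPECIES_COUNT",
    "PUBLISHED_REACTION_COUNT",
]

#: printed size of the full published model (the shipped reconstruction
#: is deliberately compact; see docs/methods.md)
PUBLISHED_SPECIES_COUNT = 189
PUBLISHED_REACTION_COUNT = 86

#: phospho/total mappings used for derived ratios; complexed forms count
#: toward the total so ratios stay within [0, 1]
RATIO_MAPPING: Dict[str, Tuple[Tuple[str, ...], Tuple[str, ...]]] = {
    "pAkt/tAkt": (
        ("pAkt", "pPIP3_Akt"),
        ("Akt", "pAkt", "PIP3_Akt", "pPIP3_Akt"),
    ),
    "pERK/tERK": (("pERK",), ("ERK", "pERK")),
}


def builtin_tables() -> Dict[str, str]:
    """Paths of the shipped species/reaction tables."""
    base = resources.files("hypoxsim.data")
    return {
        "hif_species": str(base / "species_hif.tsv"),
        "hif_reactions": str(base / "reactions_hif.tsv"),
        "tumor_species": str(base / "species_tumor.tsv"),
        "tumor_reactions": str(base / "reactions_tumor.tsv"),
    }


def load_hif_network() -> ReactionNetwork:
    t = builtin_tables()
    return load_model_tables(t["hif_species"], t["hif_reactions"])


def load_tumor_network() -> ReactionNetwork:
    t = builtin_tables()
    return load_model_tables(t["tumor_species"], t["tumor_reactions"])


@lru_cache(maxsize=1)
def builtin_model() -> ReactionNetwork:
    """Assembled integrated model (cached; treat as read-only)."""
    return assemble_integrated_model(
        load_hif_network(), load_tumor_network(), CouplingConfig()
    )
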