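"""Bundled gene sets and the human<->mouse symbol map.

The patient panel uses human symbols (upper case); the cultured-cell data
use mouse symbols (title case). The 12-gene fibrosis signature is matched
across species through the explicit table below.
"""

from __future__ import annotations

# The 12-gene heart-failure fibrosis signature: seven collagens, fibrillin,
# TIMP3, TGFB1, the chemokine CCL2 and the pericyte enzyme ACE2 (the one
# gene whose expression moves opposite to the rest in the severe subcluster).
SIGNATURE_GENES_HUMAN: list[str] = [
    "COL1A1", "COL1A2", "COL3A1", "COL6A1", "COL12A1", "COL14A1",
    "COL15A1", "FBN1", "TIMP3", "TGFB1", "CCL2", "ACE2",
]

#: Housekeeping genes used for nCounter-style normalization.
REFERENCE_GENES: list[str] = ["GAPDH", "GUSB", "PGK1", "POLR2A", "RPLP0"]

#: Filler panel genes completing the 82-gene fibrosis panel.
PANEL_FILLER_GENES: list[str] = [f"FIBG{i:02d}" for i in range(1, 66)]

#: The full 82-gene panel (12 signature + 5 reference + 65 filler).
PANEL_GENES: list[str] = SIGNATURE_GENES_HUMAN + REFERENCE_GENES + PANEL_FILLER_GENES


def _title(symbol: str) -> str:
    return symbol.capitalize()


#: Human -> mouse symbol map for every panel gene (upper case -> title case).
HUMAN_TO_MOUSE: dict[str, str] = {g: _title(g) for g in PANEL_GENES}
MOUSE_TO_HUMAN: dict[str, str] = {v: k for k, v in HUMAN_TO_MOUSE.items()}

SIGNATURE_GENES_MOUSE: list[str] = [HUMAN_TO_MOUSE[g] for g in SIGNATURE_GENES_HUMAN]


def map_symbols(genes: list[str], to: str = "mouse") -> list[str]:
    """Translate gene symbols between species.

    Parameters
    ----------
    genes
        Symbols to translate.
    to
        ``"mouse"`` (upper -> title) or ``"human"`` (title -> upper).

    Raises
    ------
    KeyError
        If any symbol has no entry in the bundled map.
    """
    table = HUMAN_TO_MOUSE if to == "mouse" else MOUSE_TO_HUMAN
    missing = [g for g in genes if g not in table]
    if missing:
        raise KeyError(f"no {to} mapping for gene symbols: {missing}")
    return [table[g] for g in genes]


# ---------------------------------------------------------------------------
# Cultured-cell (mouse) gene sets
# ---------------------------------------------------------------------------

EC_MARKERS = ["Emcn", "Pecam1", "Cdh5"]
MP_SHARED_MARKERS = ["Lyz2", "Csf1r", "Adgre1", "Cd68"]
MP1_MARKERS = ["C1qa", "C1qb", "C1qc"]
MP2_MARKERS = ["Arg1", "Mrc1", "C3"]

CONTRACTILE_GENES = ["Acta2", "Tpm2", "Tagln", "Myl9"]
MATRIX_STATE_GENES = ["Col1a1", "Col1a2"]

#: ECM activation program induced along the fibroblast trajectory.
ECM_PROGRAM_GENES = [
    "Postn", "Fn1", "Sparc", "Lox", "Serpinh1", "Serpine1", "Adamts4",
    "Eln", "Timp1", "Col4a1", "Col5a2", "Col8a1", "Ltbp2", "Fbln2",
    "Thbs1", "Ccn2", "Tnc", "Bgn", "Dcn", "Fmod", "Lum", "Vcan",
    "Sdc1", "Mmp2", "Mmp14", "Loxl1", "Pcolce", "Sulf1",
]

#: Markers of resting fibroblasts / resolution, high late in activation.
RESTING_MARKERS = ["Tcf21", "Tbx20", "Frzb", "Ccn1"]

FB_UNIQUE_MARKERS: dict[str, list[str]] = {
    "FB1": ["Cald1", "Ccnd1", "Ccnd2"],
    "FB2": ["Thy1", "Dkk3", "Scx"],
    "FB3": ["Wif1", "Gfpt2", "Sfrp2"],
    "FB4": ["Birc5", "Ube2c", "Cenpa"],
    "FB5": ["Comp", "Cilp", "Fbln1"],
    "FB6": ["Malat1", "Meg3", "Neat1"],
}

S_PHASE_GENES = [
    "Mcm2", "Mcm3", "Mcm4", "Mcm5", "Mcm6", "Mcm7", "Gins2", "Fen1",
    "Rrm2", "Slbp",
]
G2M_GENES = [
    "Top2a", "Ccnb1", "Ccna2", "Cdk1", "Aurka", "Plk1", "Birc5",
    "Ube2c", "Cenpa", "Cks2",
]

#: 17-gene proliferation score set (equal weighting).
PROLIFERATION_GENES = [
    "Ccnd1", "Ccnd2", "Mki67", "Pcna", "Top2a", "Ccnb1", "Ccna2",
    "Cdk1", "Cdk4", "Cdk6", "Ccne1", "Mcm2", "Mcm5", "Aurka", "Plk1",
    "Birc5", "Mcm6",
]

TGFB_GENES = ["Tgfb1", "Tgfb2", "Tgfb3"]

OTHER_NAMED_GENES = [
    "Vim", "Rhoa", "Des", "Smtn", "Myh11", "S100a4", "Cd44", "Ccl2",
    "Efhd2", "Gsn", "Mki67", "Pcna", "Cdk4", "Cdk6", "Ccne1",
]
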