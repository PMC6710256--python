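"""Published reference numbers used as inputs: the DSSP 8-state residue
composition of the training and test sets the method was developed on, and
the hyperparameter sets of the deployed 7-model ensembles.

These are inputs to arithmetic checks (composition mapping, model sizing),
not measurements made by this package.
"""

from __future__ import annotations

from .io_formats import ProteinRecord
from .model import ModelConfig

#: Residue counts per DSSP 8-state class for the three published set
#: compositions (training ~3.8M residues, the 2017 independent test set
#: ~652k, the 2019 set ~91k).
SS8_COMPOSITION: dict[str, dict[str, int]] = {
    "training": {
        "G": 135_498, "H": 1_306_610, "I": 714,
        "E": 800_297, "B": 41_026,
        "C": 764_391, "S": 331_075, "T": 417_815,
    },
    "test2017": {
        "G": 21_404, "H": 233_961, "I": 177,
        "E": 129_425, "B": 6_793,
        "C": 133_183, "S": 57_678, "T": 68_973,
    },
    "test2019": {
        "G": 2_300, "H": 31_854, "I": 33,
        "E": 15_411, "B": 916,
        "C": 21_605, "S": 9_804, "T": 9_452,
    },
}


def composition_records(set_name: str) -> list[ProteinRecord]:
    """Synthetic single-class records whose pooled labels reproduce a
    published set composition (one record per 8-state class)."""
    counts = SS8_COMPOSITION[set_name]
    return [
        ProteinRecord(id=f"{set_name}_{ss}", sequence="A" * n, ss8=ss * n)
        for ss, n in counts.items()
        if n > 0
    ]


# ---------------------------------------------------------------------------
# Deployed ensemble hyperparameters
# ---------------------------------------------------------------------------
# Each ensemble has 7 CBRCNN members: 3 trained on each of the two alignment
# sources (sharing one hyperparameter set) and 1 trained on the 44-wide
# concatenation.  Columns give (NF, NB), (NHF, NHB) and the stage-1 NHY;
# conv half-width 3 (kernel 7) throughout.  The 8-state members take the
# 3-state ensemble output as 3 extra inputs (25 or 47 wide).

_HP = {
    # (n_classes, concatenated): (n_inputs, nf, nb, nhf, nhb, nhy)
    (3, False): (22, 25, 30, 40, 40, 50),
    (3, True): (44, 30, 25, 45, 40, 55),
    (8, False): (25, 30, 35, 45, 55, 50),
    (8, True): (47, 36, 30, 60, 45, 48),
}


def deployed_config(n_classes: int, concatenated: bool) -> ModelConfig:
    """The published CBRCNN hyperparameter set for one member type."""
    d, nf, nb, nhf, nhb, nhy = _HP[(n_classes, concatenated)]
    return ModelConfig(
        architecture="cbrcnn", n_inputs=d, n_classes=n_classes,
        nf=nf, nb=nb, nhf=nhf, nhb=nhb, nhy=nhy,
        cofb=3, cseg=15, cwin=21,
    )


def deployed_ensemble_configs(n_classes: int) -> list[ModelConfig]:
    """Configs of the seven members of the deployed 3- or 8-state ensemble."""
    single = deployed_config(n_classes, concatenated=False)
    concat = deployed_config(n_classes, concatenated=True)
    return [single] * 6 + [concat]
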