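"""Default taxon templates for the *Papilio bootes* / *Byasa* system.

Eighteen taxa: five *P. bootes* subspecies (mimics) and thirteen *Byasa*
species (models).  Hindwing white-spot counts follow the published trait
descriptions (four-spotted western taxa, spotless northeastern taxa, the
variable *B. polyeuctes* in between); distribution ranges are condensed to
five region labels spanning western China:

- ``dulongjiang_irrawaddy`` — Dulongjiang-Irrawaddy valley, W of Gaoligong Shan
- ``nujiang_salween``       — Nujiang-Salween valley, E of Gaoligong Shan
- ``lancang_mekong_red``    — Lancang-Mekong and Yuanjiang-Red River valleys
- ``upper_yangtze``         — upper Yangtze watershed (N Yunnan / W Sichuan)
- ``qinling``               — Qinling Mountains, Shaanxi

Sympatry between two taxa is a nonempty intersection of their region sets.
"""

from __future__ import annotations

from .synthetic_wings import TaxonTemplate

REGIONS = (
    "dulongjiang_irrawaddy",
    "nujiang_salween",
    "lancang_mekong_red",
    "upper_yangtze",
    "qinling",
)

_DEF_VAR = {"spot_size": 0.01, "ground_color": 4.0, "shape": 0.02,
            "red_intensity": 0.04}
_VARIABLE = {"n_white_spots": 0.6, "spot_size": 0.02, "ground_color": 6.0,
             "shape": 0.03, "red_intensity": 0.06}


def _t(taxon_id, group, regions, spots, size=0.15, red=4, red_i=0.8,
       tail=True, tail_red=False, color=(25, 22, 28), var=_DEF_VAR):
    return TaxonTemplate(
        taxon_id=taxon_id, group=group, regions=frozenset(regions),
        n_white_spots=spots, spot_size=size, red_submarginal_count=red,
        red_intensity=red_i, has_tail=tail, tail_red_spot=tail_red,
        ground_color=color, variability=dict(var),
    )


def default_templates() -> list[TaxonTemplate]:
    """The 18-taxon study system with trait values mirroring the field taxa."""
    return [
        # --- mimics: P. bootes subspecies -----------------------------------
        _t("P_bootes_mindoni", "mimic", {"dulongjiang_irrawaddy"},
           4, size=0.17, red=5, red_i=0.85, tail_red=True, color=(28, 20, 26)),
        _t("P_bootes_parcesquamata", "mimic", {"nujiang_salween"},
           4, size=0.16, red=5, red_i=0.8, tail_red=True, color=(26, 21, 27)),
        _t("P_bootes_rubicundus", "mimic", {"lancang_mekong_red"},
           2, size=0.14, red=5, red_i=0.85, tail_red=True, color=(30, 18, 24)),
        _t("P_bootes_nigricauda", "mimic", {"upper_yangtze"},
           1, size=0.12, red=4, red_i=0.7, color=(18, 16, 20), var=_VARIABLE),
        _t("P_bootes_dealbatus", "mimic", {"qinling"},
           0, red=4, red_i=0.65, color=(16, 15, 18)),
        # --- models: Byasa species ------------------------------------------
        _t("B_latreillei", "model", {"dulongjiang_irrawaddy"},
           4, size=0.17, red=6, red_i=0.8, color=(24, 22, 26)),
        _t("B_polla", "model", {"dulongjiang_irrawaddy"},
           4, size=0.16, red=5, red_i=0.75, color=(26, 23, 27)),
        _t("B_dasarada", "model",
           {"dulongjiang_irrawaddy", "nujiang_salween", "lancang_mekong_red"},
           0, red=5, red_i=0.7, color=(20, 18, 22)),
        _t("B_daemonius", "model", {"upper_yangtze"},
           0, red=4, red_i=0.7, color=(17, 16, 20)),
        _t("B_plutonius", "model",
           {"dulongjiang_irrawaddy", "nujiang_salween", "lancang_mekong_red",
            "upper_yangtze", "qinling"},
           0, red=4, red_i=0.75, color=(15, 14, 18)),
        _t("B_rhadinus", "model", {"lancang_mekong_red"},
           1, size=0.11, red=4, red_i=0.7, color=(22, 19, 24)),
        _t("B_crassipes", "model", {"lancang_mekong_red"},
           0, red=3, red_i=0.6, tail=False, color=(19, 17, 21)),
        _t("B_genestieri", "model",
           {"nujiang_salween", "lancang_mekong_red"},
           4, size=0.16, red=5, red_i=0.75, color=(25, 22, 26)),
        _t("B_impediens", "model",
           {"lancang_mekong_red", "upper_yangtze", "qinling"},
           0, red=4, red_i=0.7, color=(16, 15, 19)),
        _t("B_nevilli", "model",
           {"dulongjiang_irrawaddy", "nujiang_salween", "lancang_mekong_red",
            "upper_yangtze"},
           4, size=0.15, red=5, red_i=0.8, color=(26, 21, 25)),
        _t("B_polyeuctes", "model", set(REGIONS),
           2, size=0.13, red=5, red_i=0.8, color=(21, 19, 23), var=_VARIABLE),
        _t("B_hedistus", "model",
           {"dulongjiang_irrawaddy", "nujiang_salween", "lancang_mekong_red",
            "upper_yangtze"},
           2, size=0.12, red=4, red_i=0.7, color=(23, 20, 24)),
        _t("B_confusus", "model", {"upper_yangtze"},
           0, red=3, red_i=0.65, color=(18, 17, 21)),
    ]


def designed_pair_templates() -> list[TaxonTemplate]:
    """Six-taxon fixture: three mimics, each sharing its spot parameters
    (count, size) and ground colour with exactly one of three models.

    Used to test end-to-end mimic-model recovery: the most similar model for
    each mimic should be its designed partner.  The three pairs are
    well-separated in pattern space — spot counts 4/2/0 and ground tones
    spanning the reddish-brown to jet-black range of the real taxa — so that
    a faithful pipeline should rank the partner first.
    """
    pairs = [  # (spots, spot_size, ground colour)
        (4, 0.17, (52, 30, 36)),
        (2, 0.13, (28, 21, 27)),
        (0, 0.15, (10, 11, 15)),
    ]
    taxa = []
    for i, (k, s, c) in enumerate(pairs):
        taxa.append(_t(f"mimic_{i}", "mimic", {f"r{i}"}, k, size=s, color=c,
                       red=4 + i, tail_red=True))
        taxa.append(_t(f"model_{i}", "model", {f"r{i}"}, k, size=s, color=c,
                       red=4 + i))
    return taxa
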