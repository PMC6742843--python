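"""ROI label sets.

:func:`conn_style_labels` ships a synthetic stand-in for the 132-parcel
atlas used in ROI-ROI connectivity toolboxes: 91 cortical and 15 subcortical
labels following Harvard-Oxford naming conventions plus 26 cerebellar labels
following AAL naming conventions, with the canonical seed subsets (8 basal
ganglia, 2 thalamus, 26 cerebellum). Only the composition (counts and seed
subsets) is normative; the label strings are conventional names, not a
redistribution of any atlas file.

:func:`synthetic_labels` builds small generic label sets for simulation at
desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_HO_BILATERAL = [
    "Frontal Pole",
    "Insular Cortex",
    "Superior Frontal Gyrus",
    "Middle Frontal Gyrus",
    "Inferior Frontal Gyrus, pars triangularis",
    "Inferior Frontal Gyrus, pars opercularis",
    "Precentral Gyrus",
    "Temporal Pole",
    "Superior Temporal Gyrus, anterior division",
    "Superior Temporal Gyrus, posterior division",
    "Middle Temporal Gyrus, anterior division",
    "Middle Temporal Gyrus, posterior division",
    "Middle Temporal Gyrus, temporooccipital part",
    "Inferior Temporal Gyrus, anterior division",
    "Inferior Temporal Gyrus, posterior division",
    "Inferior Temporal Gyrus, temporooccipital part",
    "Postcentral Gyrus",
    "Superior Parietal Lobule",
    "Supramarginal Gyrus, anterior division",
    "Supramarginal Gyrus, posterior division",
    "Angular Gyrus",
    "Lateral Occipital Cortex, superior division",
    "Lateral Occipital Cortex, inferior division",
    "Intracalcarine Cortex",
    "Juxtapositional Lobule Cortex",
    "Paracingulate Gyrus",
    "Cuneal Cortex",
    "Frontal Orbital Cortex",
    "Parahippocampal Gyrus, anterior division",
    "Parahippocampal Gyrus, posterior division",
    "Lingual Gyrus",
    "Temporal Fusiform Cortex, anterior division",
    "Temporal Fusiform Cortex, posterior division",
    "Temporal Occipital Fusiform Cortex",
    "Occipital Fusiform Gyrus",
    "Frontal Operculum Cortex",
    "Central Opercular Cortex",
    "Parietal Operculum Cortex",
    "Planum Polare",
    "Heschl's Gyrus",
    "Planum Temporale",
    "Supracalcarine Cortex",
    "Occipital Pole",
]

_HO_MIDLINE = [
    "Frontal Medial Cortex",
    "Subcallosal Cortex",
    "Cingulate Gyrus, anterior division",
    "Cingulate Gyrus, posterior division",
    "Precuneous Cortex",
]

_SUBCORTICAL_BILATERAL = [
    "Thalamus",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Hippocampus",
    "Amygdala",
    "Accumbens",
]

_AAL_CEREBELLAR_BILATERAL = [
    "Cerebelum Crus1",
    "Cerebelum Crus2",
    "Cerebelum 3",
    "Cerebelum 4 5",
    "Cerebelum 6",
    "Cerebelum 7b",
    "Cerebelum 8",
    "Cerebelum 9",
    "Cerebelum 10",
]

_AAL_VERMIS = [
    "Vermis 1 2",
    "Vermis 3",
    "Vermis 4 5",
    "Vermis 6",
    "Vermis 7",
    "Vermis 8",
    "Vermis 9",
    "Vermis 10",
]

_BASAL_GANGLIA = ["Caudate", "Putamen", "Pallidum", "Accumbens"]


def _lateralise(names: list[str]) -> list[str]:
    out = []
    for name in names:
        out.append(f"{name} L")
        out.append(f"{name} R")
    return out


@dataclass(frozen=True)
class RoiLabelSet:
    """An ordered ROI parcellation with designated seed subsets.

    The seed subsets (basal ganglia, thalamus, cerebellum) define which
    ROI-ROI connections enter the restricted group comparison: each seed is
    tested against every other ROI in the set.
    """

    cortical: tuple[str, ...]
    subcortical: tuple[str, ...]
    cerebellar: tuple[str, ...]
    basal_ganglia: tuple[str, ...]
    thalamus: tuple[str, ...]
    cerebellum_seeds: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        labels = self.all_labels
        if len(set(labels)) != len(labels):
            raise ValueError("ROI labels must be unique")
        pool = set(self.subcortical) | set(self.cerebellar)
        for subset, name in (
            (self.basal_ganglia, "basal_ganglia"),
            (self.thalamus, "thalamus"),
            (self.cerebellum_seeds, "cerebellum"),
        ):
            missing = set(subset) - pool
            if missing:
                raise ValueError(
                    f"seed subset {name} contains labels outside the "
                    f"subcortical/cerebellar pool: {sorted(missing)}"
                )

    @property
    def all_labels(self) -> list[str]:
        return list(self.cortical) + list(self.subcortical) + list(self.cerebellar)

    @property
    def seeds(self) -> list[str]:
        """Basal ganglia + thalamus + cerebellar seed ROIs, in atlas order."""
        return (
            list(self.basal_ganglia)
            + list(self.thalamus)
            + list(self.cerebellum_seeds)
        )

    @property
    def n_rois(self) -> int:
        return len(self.all_labels)


def conn_style_labels() -> RoiLabelSet:
    """The full 132-label set: 91 cortical, 15 subcortical, 26 cerebellar.

    Seed subsets: 8 basal ganglia ROIs (caudate, putamen, pallidum,
    accumbens, both hemispheres), 2 thalamic ROIs, all 26 cerebellar ROIs.
    """
    cortical = tuple(_lateralise(_HO_BILATERAL) + _HO_MIDLINE)
    subcortical = tuple(_lateralise(_SUBCORTICAL_BILATERAL) + ["Brain-Stem"])
    cerebellar = tuple(_lateralise(_AAL_CEREBELLAR_BILATERAL) + _AAL_VERMIS)
    return RoiLabelSet(
        cortical=cortical,
        subcortical=subcortical,
        cerebellar=cerebellar,
        basal_ganglia=tuple(_lateralise(_BASAL_GANGLIA)),
        thalamus=("Thalamus L", "Thalamus R"),
        cerebellum_seeds=cerebellar,
    )


def synthetic_labels(n_rois: int = 40, n_seeds: int = 8) -> tuple[list[str], list[str]]:
    """Generic labels for desk-scale simulation.

    Returns ``(labels, seed_labels)`` where the first ``n_seeds`` ROIs play
    the role of the subcortical seed set and the remainder stand in for
    cortex.
    """
    if not 0 < n_seeds < n_rois:
        raise ValueError("need 0 < n_seeds < n_rois")
    width = len(str(n_rois))
    seeds = [f"seed{str(i + 1).zfill(width)}" for i in range(n_seeds)]
    others = [f"roi{str(i + 1).zfill(width)}" for i in range(n_rois - n_seeds)]
    return seeds + others, seeds
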