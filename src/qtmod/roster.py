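"""Subcortical-structure roster and its expansion into phenotype columns.

The analysis is phrased over Freesurfer's automated subcortical
segmentation: 22 named regions of interest, 13 of which are bilateral
(left and right measured separately) and 9 unilateral (brainstem, the
five corpus-callosum segments, third/fourth ventricle, CSF). Expanding
the bilateral entries yields the 35 volumetric phenotypes that are
clustered into modules.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["RosterEntry", "RoiRoster", "default_roster"]


@dataclass(frozen=True)
class RosterEntry:
    """One segmentation label: ``bilateral`` entries expand to L/R phenotypes.

    ``typical_volume`` is a rough adult volume in mm^3 (per side for
    bilateral structures) used by the synthetic generator to put each
    phenotype on an anatomically plausible scale.
    """

    roi: str
    bilateral: bool
    typical_volume: float


class RoiRoster:
    """Ordered collection of segmentation labels."""

    def __init__(self, entries: list[RosterEntry]):
        ids = [e.roi for e in entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ROI labels in roster")
        self.entries = list(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def expand(self) -> list[str]:
        """Phenotype column names, bilateral entries emitting Left-/Right-.

        Order is stable: entries in roster order, Left before Right.
        """
        out: list[str] = []
        for e in self.entries:
            if e.bilateral:
                out.append(f"Left-{e.roi}")
                out.append(f"Right-{e.roi}")
            else:
                out.append(e.roi)
        if len(set(out)) != len(out):
            raise ValueError("roster expansion produced duplicate phenotype ids")
        return out

    def typical_volumes(self) -> dict[str, float]:
        """Typical volume (mm^3) per expanded phenotype."""
        out: dict[str, float] = {}
        for e in self.entries:
            if e.bilateral:
                out[f"Left-{e.roi}"] = e.typical_volume
                out[f"Right-{e.roi}"] = e.typical_volume
            else:
                out[e.roi] = e.typical_volume
        return out


#: anatomical module ids used by the synthetic generator's ground truth:
#: 1 limbic system, 2 corpus callosum, 3 thalamus/cerebellum/brainstem/
#: pallidum, 4 neostriatum, 5 ventricular system.
ANATOMICAL_MODULES: dict[str, int] = {
    "Accumbens-area": 1,
    "Amygdala": 1,
    "Hippocampus": 1,
    "CC_Anterior": 2,
    "CC_Mid_Anterior": 2,
    "CC_Central": 2,
    "CC_Mid_Posterior": 2,
    "CC_Posterior": 2,
    "Brain-Stem": 3,
    "Cerebellum-Cortex": 3,
    "Cerebellum-White-Matter": 3,
    "Pallidum": 3,
    "Thalamus-Proper": 3,
    "VentralDC": 3,
    "Caudate": 4,
    "Putamen": 4,
    "CSF": 5,
    "Choroid-plexus": 5,
    "Inf-Lat-Vent": 5,
    "Lateral-Ventricle": 5,
    "3rd-Ventricle": 5,
    "4th-Ventricle": 5,
}


def default_roster() -> RoiRoster:
    """The standard 22-label subcortical roster (35 phenotypes expanded)."""
    rows = [
        ("Accumbens-area", True, 600.0),
        ("Amygdala", True, 1600.0),
        ("Brain-Stem", False, 21000.0),
        ("Caudate", True, 3600.0),
        ("CC_Anterior", False, 900.0),
        ("CC_Central", False, 450.0),
        ("CC_Mid_Anterior", False, 450.0),
        ("CC_Mid_Posterior", False, 450.0),
        ("CC_Posterior", False, 950.0),
        ("CSF", False, 1100.0),
        ("Cerebellum-Cortex", True, 52000.0),
        ("Cerebellum-White-Matter", True, 14000.0),
        ("Choroid-plexus", True, 800.0),
        ("Hippocampus", True, 3900.0),
        ("Inf-Lat-Vent", True, 500.0),
        ("Lateral-Ventricle", True, 16000.0),
        ("Pallidum", True, 1700.0),
        ("Putamen", True, 5200.0),
        ("Thalamus-Proper", True, 7100.0),
        ("VentralDC", True, 4100.0),
        ("3rd-Ventricle", False, 1600.0),
        ("4th-Ventricle", False, 1900.0),
    ]
    return RoiRoster([RosterEntry(r, b, v) for r, b, v in rows])


def anatomical_assignment(roster: RoiRoster) -> dict[str, int]:
    """Ground-truth module id per expanded phenotype (sizes 6/5/11/4/9)."""
    out: dict[str, int] = {}
    for e in roster.entries:
        mod = ANATOMICAL_MODULES[e.roi]
        if e.bilateral:
            out[f"Left-{e.roi}"] = mod
            out[f"Right-{e.roi}"] = mod
        else:
            out[e.roi] = mod
    return out
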