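"""End-to-end analysis: images -> registration -> binarization ->
edge-aligned profiles -> positionwise comparison.

The unit of work is a patient-control pair: the patient's angiograms are
registered to its NIR-FAF, the large-vessel mask is derived from the SVC,
each slab is binarized, VD/FD profiles are sampled along the three
directions and re-indexed to the patient's APA border; the matched control
is profiled on the same offsets using the patient's border distance (a
healthy control has no border of its own). Cohort-level fitting stacks the
pairs per metric and direction into :class:`~octaprof.stats.AlignedCohort`
objects and runs the paired positionwise comparison.

The global thresholds of the binarization chain are computed on the full
frame, exactly once per slab image: windowed shortcuts would let the
threshold drift with the local mix of preserved and atrophic texture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binarize import (BinarizationParams, NormalCCDatabase, binarize_cc,
                       binarize_plexus, cc_threshold_from_normals,
                       large_vessel_mask)
from .io import AngiogramSet, EnFaceImage
from .nirfaf import APAEdge, detect_edge, has_apa
from .profiles import (ProfileSeries, align_to_edge, build_series,
                       compute_profile, il_profile, profiles_to_frame)
from .register import SimilarityTransform, apply_transform, estimate_transform
from .stats import AlignedCohort, PairedProfileComparison

__all__ = ["PairAnalysis", "CohortAnalysis", "analyze_pair", "analyze_cohort"]

DIRECTIONS = ("superior", "inferior", "temporal")
SLAB_METRIC = {"SVC": "VD", "DCC": "VD", "CC": "FD"}


@dataclass
class PairAnalysis:
    """Analysis products of one patient-control pair."""

    pair_id: str
    transform: SimilarityTransform | None
    edges: dict                       # direction -> APAEdge
    apa_usable: bool
    apa_reason: str
    profiles: list = field(default_factory=list)    # aligned ProfileSeries
    il_profiles: list = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return profiles_to_frame(self.profiles + self.il_profiles)


@dataclass
class CohortAnalysis:
    """Cohort-level products: per-pair analyses plus fitted comparisons."""

    pairs: list
    results: dict                     # (metric, direction) -> results
    excluded: dict                    # pair_id -> reason

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.summary_row() for r in self.results.values()])

    def profiles_frame(self) -> pd.DataFrame:
        frames = [p.frame().assign(pair_id=p.pair_id) for p in self.pairs]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def analyze_pair(
    patient: AngiogramSet,
    patient_nirfaf: EnFaceImage,
    control: AngiogramSet,
    control_nirfaf: EnFaceImage,
    cc_threshold: float | None = None,
    normal_db: NormalCCDatabase | None = None,
    params: BinarizationParams | None = None,
    pre_registered: bool = False,
    register_controls: bool = False,
    slabs: tuple = ("SVC", "DCC", "CC"),
    manual_edges: dict | None = None,
    pair_id: str | None = None,
) -> PairAnalysis:
    """Run the full single-pair analysis.

    ``cc_threshold`` (or ``normal_db`` to derive it) is required when the
    CC slab is analyzed. ``manual_edges`` (direction -> edge index)
    overrides automatic edge detection. With ``pre_registered`` the
    angiogram grids are taken to coincide with the NIR-FAF grid.
    """
    n = patient_nirfaf.n_px
    if params is None:
        params = BinarizationParams.for_grid(n)
    if "CC" in slabs and cc_threshold is None:
        if normal_db is None:
            raise ValueError("CC analysis needs cc_threshold or normal_db")
        cc_threshold = cc_threshold_from_normals(normal_db, params.cc_sd_multiplier)
    pair_id = pair_id or patient.subject_id

    transform = None
    if pre_registered:
        p_valid = np.ones((n, n), dtype=bool)
    else:
        transform = estimate_transform(patient.svc, patient_nirfaf)
        patient, p_valid = apply_transform(patient, transform)
    if register_controls and not pre_registered:
        t_c = estimate_transform(control.svc, control_nirfaf)
        control, c_valid = apply_transform(control, t_c)
    else:
        c_valid = np.ones((n, n), dtype=bool)

    series = {d: build_series(n, patient_nirfaf.scale_um_per_px, d,
                              patient_nirfaf.fovea_xy_px,
                              patient_nirfaf.temporal_side)
              for d in DIRECTIONS}

    masks = {"patient": large_vessel_mask(patient.svc, params),
             "control": large_vessel_mask(control.svc, params)}
    il = {d: il_profile(patient_nirfaf, series[d], masks["patient"])
          for d in DIRECTIONS}
    if manual_edges:
        edges = {d: APAEdge(d, True, k, k * 0.1) for d, k in manual_edges.items()}
    else:
        edges = {d: detect_edge(il[d]) for d in DIRECTIONS}
    usable, reason = has_apa(edges)

    analysis = PairAnalysis(pair_id, transform, edges, usable, reason)
    for d in DIRECTIONS:
        if edges[d].detected:
            analysis.il_profiles.append(align_to_edge(il[d], edges[d].edge_index))
        else:
            analysis.il_profiles.append(il[d])
    if not usable:
        return analysis

    sets = {"patient": (patient, p_valid), "control": (control, c_valid)}

    for slab in slabs:
        metric = SLAB_METRIC[slab]
        for role, (angio, valid) in sets.items():
            img = angio.slabs()[slab]
            if slab == "CC":
                bmap = binarize_cc(img, cc_threshold, masks[role], valid)
            else:
                bmap = binarize_plexus(img, params, masks[role], valid)
            for d in DIRECTIONS:
                prof = compute_profile(bmap, series[d], metric,
                                       subject_id=angio.subject_id, role=role)
                analysis.profiles.append(
                    align_to_edge(prof, edges[d].edge_index))
    return analysis


def analyze_cohort(
    pairs: list,
    alpha: float = 0.05,
    min_run: int = 5,
    slabs: tuple = ("SVC", "DCC", "CC"),
    **pair_kwargs,
) -> CohortAnalysis:
    """Analyze a list of pairs and fit the positionwise comparisons.

    ``pairs`` is a list of tuples ``(pair_id, patient AngiogramSet,
    patient NIR-FAF, control AngiogramSet, control NIR-FAF)``. Pairs whose
    APA border cannot be located in all three directions are excluded from
    the comparison (reported in ``excluded``).
    """
    analyses, excluded = [], {}
    for pair_id, pat, pat_nir, ctl, ctl_nir in pairs:
        a = analyze_pair(pat, pat_nir, ctl, ctl_nir, slabs=slabs,
                         pair_id=pair_id, **pair_kwargs)
        if a.apa_usable:
            analyses.append(a)
        else:
            excluded[pair_id] = a.apa_reason

    results = {}
    for slab in slabs:
        metric = SLAB_METRIC[slab]
        for d in DIRECTIONS:
            triplets = []
            for a in analyses:
                pat_p = _find_profile(a, slab, d, "patient")
                ctl_p = _find_profile(a, slab, d, "control")
                if pat_p is not None and ctl_p is not None:
                    triplets.append((a.pair_id, pat_p, ctl_p))
            if not triplets:
                continue
            label = metric if slab == "CC" else f"VD[{slab}]"
            cohort = AlignedCohort.from_profiles(label, d, triplets)
            results[(label, d)] = PairedProfileComparison(
                cohort, alpha=alpha, min_run=min_run).fit()
    return CohortAnalysis(analyses, results, excluded)


def _find_profile(a: PairAnalysis, slab: str, direction: str,
                  role: str) -> ProfileSeries | None:
    for p in a.profiles:
        if p.modality == slab and p.direction == direction and p.role == role:
            return p
    return None
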