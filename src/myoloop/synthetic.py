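"""Virtual-patient generation.

Forward-simulates 18-segment strain datasets from a known (hidden)
parameter vector — an infarct pattern of regional NCVF and stiffness —
and adds measurement-like noise, so the estimation pipeline can be
exercised and validated end to end without clinical data.  Presets mimic
two common infarct morphologies: a transmural anteroseptal infarct and a
nontransmural apical infarct.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np

from .estimation import (ParameterVector, SegmentDataset, Uncertainty,
                         dataset_from_beat)
from .segments import SEGMENTS_18, build_segment_model

__all__ = ["VirtualPatientSpec", "generate", "make_followup_pair",
           "PRESET_PATTERNS"]

PRESET_PATTERNS = {
    # LAD-territory transmural infarct: severe dysfunction in the
    # anteroseptal/anterior mid and apical segments
    "anteroseptal_transmural": {
        "mid_anteroseptal": 0.8, "apical_anteroseptal": 0.8,
        "mid_anterior": 0.7, "apical_anterior": 0.8,
        "apical_inferoseptal": 0.6,
    },
    # distal-LAD nontransmural infarct: moderate dysfunction limited to
    # the apical cap
    "apical_nontransmural": {
        "apical_anterior": 0.4, "apical_anteroseptal": 0.4,
        "apical_inferoseptal": 0.4, "apical_inferior": 0.4,
        "apical_inferolateral": 0.4, "apical_anterolateral": 0.4,
    },
}


@dataclass
class VirtualPatientSpec:
    """Ground truth and acquisition settings of one virtual patient."""

    pattern: dict | str = "anteroseptal_transmural"
    k_ecm: dict = field(default_factory=dict)   # per-segment overrides
    heart_rate: float = 71.0
    sv: float = 72.0               # ml, true stroke volume
    noise: Uncertainty = field(default_factory=Uncertainty)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.pattern, str):
            try:
                self.pattern = dict(PRESET_PATTERNS[self.pattern])
            except KeyError:
                raise KeyError(
                    f"unknown preset pattern {self.pattern!r}; available: "
                    f"{sorted(PRESET_PATTERNS)}") from None
        unknown = set(self.pattern) - set(SEGMENTS_18)
        if unknown:
            raise ValueError(f"pattern names unknown segments: {unknown}")
        for v in self.pattern.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("pattern NCVF values must lie in [0, 1]")
        if any(v < 0 for v in
               (self.noise.strain, self.noise.edv, self.noise.ef)):
            raise ValueError("noise levels must be non-negative")

    def true_params(self) -> ParameterVector:
        pv = ParameterVector.reference()
        pv.sv = self.sv
        for s, v in self.pattern.items():
            pv.ncvf[SEGMENTS_18.index(s)] = v
        for s, v in self.k_ecm.items():
            pv.k_ecm[SEGMENTS_18.index(s)] = v
        return pv


def _simulate_truth(spec: VirtualPatientSpec) -> SegmentDataset:
    """Converged noise-free forward simulation at the true parameters."""
    pv = spec.true_params()
    m = build_segment_model(heart_rate=spec.heart_rate, sv_target=pv.sv)
    for i, name in enumerate(m.patch_names):
        if name in SEGMENTS_18:
            j = SEGMENTS_18.index(name)
            m.set_patch(i, ncvf=float(pv.ncvf[j]),
                        k_ecm_nc=float(pv.k_ecm[j]))
    m.set_contraction_duration(pv.cd)
    beat = m.run_to_steady_state(beats_max=200)
    return dataset_from_beat(beat, spec.heart_rate)


def generate(spec: VirtualPatientSpec
             ) -> tuple[SegmentDataset, ParameterVector]:
    """Noisy 18-segment dataset plus the hidden ground-truth parameters.

    Strain samples receive independent additive Gaussian noise at the
    per-sample strain uncertainty; EDV and EF receive one Gaussian
    perturbation each at their uncertainty scales.  Fully reproducible
    from ``spec.seed``.
    """
    clean = _simulate_truth(spec)
    rng = np.random.default_rng(spec.seed)
    noisy = SegmentDataset(
        time=clean.time.copy(),
        strain=clean.strain + rng.normal(0.0, spec.noise.strain,
                                         clean.strain.shape),
        heart_rate=clean.heart_rate,
        edv=clean.edv + rng.normal(0.0, spec.noise.edv),
        ef=clean.ef + rng.normal(0.0, spec.noise.ef))
    return noisy, spec.true_params()


def make_followup_pair(spec: VirtualPatientSpec, delta_ncvf: dict
                       ) -> tuple[SegmentDataset, SegmentDataset,
                                  ParameterVector, ParameterVector]:
    """Baseline and follow-up datasets of one patient.

    The follow-up spec shifts segmental NCVF by ``delta_ncvf`` (clipped to
    [0, 1] with a warning), emulating partial functional recovery or
    deterioration between an acute exam and a later follow-up.
    Returns (baseline_data, followup_data, baseline_truth, followup_truth).
    """
    unknown = set(delta_ncvf) - set(SEGMENTS_18)
    if unknown:
        raise ValueError(f"delta names unknown segments: {unknown}")
    fu = copy.deepcopy(spec)
    fu.seed = spec.seed + 7919
    for s, d in delta_ncvf.items():
        new = fu.pattern.get(s, 0.0) + d
        if new < 0.0 or new > 1.0:
            warnings.warn(
                f"follow-up NCVF for {s} clipped to [0, 1] (was {new:.2f})",
                stacklevel=2)
            new = min(max(new, 0.0), 1.0)
        fu.pattern[s] = new
    base_data, base_truth = generate(spec)
    fu_data, fu_truth = generate(fu)
    return base_data, fu_data, base_truth, fu_truth
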