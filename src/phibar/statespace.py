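"""Four-axis state descriptors: strengths and topographies relative to baseline.

A conscious-state descriptor combines (i) overall integrated-information
strength and (ii) overall connectivity strength, both min-max normalized to
the baseline state's range, with (iii, iv) the Pearson topographic
similarity of the regional phi_bar map and of the node-degree map to the
baseline maps.  States with baseline-like strengths but reorganized
topographies (e.g. anesthetic burst activity) separate on the similarity
axes even when the strength axes cannot distinguish them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import ConfigurationError

__all__ = ["StateMetrics", "StateDescriptor", "normalize_strength",
           "topographic_similarity", "build_descriptor", "descriptor_area"]


@dataclass
class StateMetrics:
    """Per-state inputs to the descriptor for one band.

    ``phi_bar_samples`` / ``degree_samples`` are per-epoch (or per-segment)
    values used only for the baseline min-max range.
    """

    phi_bar: float
    avg_degree: float
    phi_map: np.ndarray
    degree_map: np.ndarray
    phi_bar_samples: np.ndarray | None = None
    degree_samples: np.ndarray | None = None


@dataclass
class StateDescriptor:
    """The four normalized axes for one state, plus the radar-polygon area."""

    state: str
    rel_phi: float
    rel_degree: float
    sim_phi_topo: float
    sim_degree_topo: float
    area: float
    clipped: bool = False
    provenance: dict = field(default_factory=dict)


def normalize_strength(value: float, baseline_min: float, baseline_max: float,
                       ) -> tuple[float, bool]:
    """(value - min) / (max - min), clipped to [0, 1] with a flag."""
    if not baseline_max > baseline_min:
        raise ConfigurationError("degenerate baseline range for normalization")
    x = (value - baseline_min) / (baseline_max - baseline_min)
    clipped = x < 0 or x > 1
    return float(np.clip(x, 0.0, 1.0)), clipped


def topographic_similarity(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Pearson correlation between two per-channel maps.

    Invariant to affine rescaling of either map, so raw and baseline-
    normalized maps give the same similarity.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigurationError("maps must be 1-D and share the channel set")
    if len(a) < 3:
        raise ConfigurationError("need >= 3 channels for a topographic similarity")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ConfigurationError("constant map: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def descriptor_area(sim_phi: float, rel_phi: float, sim_degree: float,
                    rel_degree: float) -> float:
    """Radar-polygon area over axes (sim_phi, rel_phi, sim_degree, rel_degree).

    Similarities are rescaled from [-1, 1] to [0, 1] for the geometry only;
    the four radii sit on orthogonal axes, so the quadrilateral area is
    ``(r1 r2 + r2 r3 + r3 r4 + r4 r1) / 2`` — maximal (2.0) exactly when the
    state matches baseline on all four axes.
    """
    r = [(sim_phi + 1) / 2, rel_phi, (sim_degree + 1) / 2, rel_degree]
    return 0.5 * (r[0] * r[1] + r[1] * r[2] + r[2] * r[3] + r[3] * r[0])


def build_descriptor(metrics_by_state: dict[str, StateMetrics],
                     baseline_label: str = "baseline",
                     provenance: dict | None = None) -> list[StateDescriptor]:
    """Assemble one 4-axis descriptor per state, normalized to baseline.

    Strengths are normalized by the min/max of the baseline's per-epoch
    samples (falling back to ±10% of the baseline scalar when samples are
    absent); values outside the baseline range clip to [0, 1] with a flag.
    The baseline's own descriptor is (1, 1, 1, 1) by construction.
    """
    if baseline_label not in metrics_by_state:
        raise ConfigurationError(f"baseline state {baseline_label!r} missing")
    base = metrics_by_state[baseline_label]
    for state, m in metrics_by_state.items():
        for attr in ("phi_bar", "avg_degree", "phi_map", "degree_map"):
            if getattr(m, attr, None) is None:
                raise ConfigurationError(f"state {state!r} lacks metric {attr!r}")

    def baseline_range(samples, scalar):
        if samples is not None and len(samples) >= 2 and np.ptp(samples) > 0:
            return float(np.min(samples)), float(np.max(samples))
        pad = 0.1 * abs(scalar) if scalar != 0 else 1e-6
        return scalar - pad, scalar + pad

    phi_lo, phi_hi = baseline_range(base.phi_bar_samples, base.phi_bar)
    deg_lo, deg_hi = baseline_range(base.degree_samples, base.avg_degree)

    out = []
    for state, m in metrics_by_state.items():
        if state == baseline_label:
            out.append(StateDescriptor(state=state, rel_phi=1.0, rel_degree=1.0,
                                       sim_phi_topo=1.0, sim_degree_topo=1.0,
                                       area=descriptor_area(1.0, 1.0, 1.0, 1.0),
                                       provenance=dict(provenance or {})))
            continue
        rel_phi, c1 = normalize_strength(m.phi_bar, phi_lo, phi_hi)
        rel_deg, c2 = normalize_strength(m.avg_degree, deg_lo, deg_hi)
        if c1 or c2:
            warnings.warn(f"state {state!r}: strength outside baseline range, clipped")

        def sim_or_zero(a, b, which):
            # a constant map (e.g. an empty suppression-state graph) has no
            # defined topography; its similarity axis reports 0 with a warning
            try:
                return topographic_similarity(a, b)
            except ConfigurationError:
                warnings.warn(f"state {state!r}: constant {which} map, similarity "
                              "reported as 0")
                return 0.0

        sim_phi = sim_or_zero(m.phi_map, base.phi_map, "phi")
        sim_deg = sim_or_zero(m.degree_map, base.degree_map, "degree")
        out.append(StateDescriptor(
            state=state, rel_phi=rel_phi, rel_degree=rel_deg,
            sim_phi_topo=sim_phi, sim_degree_topo=sim_deg,
            area=descriptor_area(sim_phi, rel_phi, sim_deg, rel_deg),
            clipped=c1 or c2, provenance=dict(provenance or {}),
        ))
    return out
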