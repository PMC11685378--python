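"""Synthetic multimodal cohorts with planted core-periphery structure.

Nothing in the public record provides per-subject MC/SC/FC matrices for a
clinical MS cohort, so this module generates cohorts that carry the
statistical structure the analysis assumes, together with the ground truth
needed for recovery tests:

* a planted core: a subset of nodes whose mutual (core-core) edges are
  stronger, on average, than core-periphery edges, which are in turn
  stronger than periphery-periphery edges (``w_cc > w_cp > w_pp > 0``);
* regional gray-matter volumes that depend linearly on age, sex and TIV,
  with node-specific noise, plus disease-related atrophy concentrated on
  core nodes;
* a *targeted attack* for patients: every edge incident to a node with core
  affinity ``a_i`` is multiplied by ``(1 - delta * max(a_i, a_j))``, where
  ``delta`` in [0, 1] scales with disease severity.  delta = 0 for controls;
  its phenotype means are ordered CIS < RRMS < SPMS with PPMS intermediate;
* clinical scores that are monotone noisy functions of delta (EDSS up,
  SDMT z down, BPF down, lesion volume up);
* optional additive/multiplicative site effects, applied last, for
  harmonization tests.

All generator constants are stand-ins chosen to look like a plausible 3T
multicenter cohort; downstream assertions about them are qualitative
(ordering, sign, calibration), never exact effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CohortData, Parcellation, make_parcellation, validate_cohort_table
from .layers import ConnectivityLayer, MultiplexNetwork, svd_normalize

__all__ = [
    "SyntheticTruth",
    "DEFAULT_PARAMS",
    "simulate_cohort",
    "planted_core_multiplex",
    "apply_targeted_attack",
]


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator."""

    core_nodes: list[str]
    core_indices: np.ndarray
    affinity: np.ndarray                       # per-node core affinity in [0, 1]
    attack_strength: dict[str, float]          # subject id -> delta
    site_offsets: dict[str, dict[str, float]]  # site -> {volume_shift, volume_scale, ...}
    covariate_slopes: dict[str, float]
    weight_means: dict[str, tuple[float, float, float]]  # per modality (w_cc, w_cp, w_pp)


# Study conditions of the generator.  Phenotype mix mirrors a large MS
# cohort (mostly relapsing-remitting); delta means are ordered
# CIS < RRMS < SPMS with PPMS intermediate.
DEFAULT_PARAMS: dict = {
    "sc_weight_means": (40.0, 12.0, 4.0),    # gamma-mean streamline weights (cc, cp, pp)
    "sc_gamma_shape": 3.0,
    "fc_corr_means": (0.5, 0.25, 0.10),      # block-mean correlations (cc, cp, pp)
    "fc_corr_noise": 0.12,
    "volume_base_range": (4.0, 12.0),        # ml, per-node baseline
    "volume_noise_sd": 0.4,                  # ml
    "covariate_slopes": {"age": -0.02, "sex": 0.5, "tiv": 0.003},
    "atrophy_scale": 0.3,                    # fractional volume loss at delta=1 on core nodes
    "delta_by_phenotype": {"CIS": 0.15, "RRMS": 0.30, "SPMS": 0.55, "PPMS": 0.45},
    "delta_sd": 0.08,
    "edss_model": {"intercept": 2.0, "slope": 5.0, "noise_sd": 0.7},
    "sdmt_model": {"slope": -2.5, "noise_sd": 0.8},
    "bpf_model": {"intercept": 0.80, "delta_slope": -0.06,
                  "age_slope": -0.0008, "noise_sd": 0.02},
    "tlv_model": {"shape": 2.0, "base_mean": 2.0, "delta_gain": 6.0},
    "site_volume_shift_sd": 0.5,             # ml, additive per-site location on volumes
    "site_volume_scale_sd": 0.05,            # multiplicative per-site scale on volumes
    "site_edge_scale_sd": 0.10,              # multiplicative per-site scale on raw SC
    "site_fc_shift_sd": 0.05,                # additive per-site shift on FC correlations
}

DEFAULT_PHENOTYPE_MIX = {"CIS": 0.04, "RRMS": 0.78, "SPMS": 0.11, "PPMS": 0.07}

_PHENOTYPES = ("CIS", "RRMS", "SPMS", "PPMS")


def _merge_params(params: Mapping | None) -> dict:
    merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_PARAMS.items()}
    if params:
        for key, val in params.items():
            if key not in merged:
                raise ValueError(
                    f"unknown simulation parameter {key!r}; valid: {sorted(merged)}"
                )
            if isinstance(merged[key], dict):
                unknown = set(val) - set(merged[key])
                if unknown:
                    raise ValueError(f"unknown keys {sorted(unknown)} in parameter {key!r}")
                merged[key].update(val)
            else:
                merged[key] = val
    return merged


def _block_matrix(rng, n, core_mask, means, draw):
    """Symmetric zero-diagonal matrix with blockwise-distributed weights."""
    w_cc, w_cp, w_pp = means
    mean_mat = np.where(
        core_mask[:, None] & core_mask[None, :], w_cc,
        np.where(core_mask[:, None] | core_mask[None, :], w_cp, w_pp),
    )
    iu, ju = np.triu_indices(n, k=1)
    vals = draw(rng, mean_mat[iu, ju])
    out = np.zeros((n, n))
    out[iu, ju] = vals
    out += out.T
    return out


def apply_targeted_attack(multiplex, affinity, delta: float):
    """Scale every edge (i, j) by ``(1 - delta * max(affinity_i, affinity_j))``.

    Accepts a MultiplexNetwork (returns a new one, layers re-normalized is
    the caller's concern) or a plain weight matrix / list of matrices.
    """
    if not (0.0 <= delta <= 1.0):
        raise ValueError(f"delta must be in [0, 1], got {delta}")
    a = np.asarray(affinity, dtype=float).ravel()
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("affinity values must lie in [0, 1]")
    factor = 1.0 - delta * np.maximum(a[:, None], a[None, :])

    def _scale(w):
        out = np.asarray(w, dtype=float) * factor
        np.fill_diagonal(out, 0.0)
        return out

    if isinstance(multiplex, MultiplexNetwork):
        layers = tuple(
            ConnectivityLayer(lay.kind, _scale(lay.weights), list(lay.node_labels))
            for lay in multiplex.layers
        )
        return MultiplexNetwork(layers=layers, node_labels=list(multiplex.node_labels))
    if isinstance(multiplex, np.ndarray):
        return _scale(multiplex)
    return [_scale(w) for w in multiplex]


def planted_core_multiplex(
    n_nodes: int,
    core_set: Sequence[int],
    weight_means: tuple[float, float, float] = (1.0, 0.5, 0.1),
    noise: float = 0.0,
    seed=None,
    n_layers: int = 3,
    node_labels: Sequence[str] | None = None,
) -> tuple[MultiplexNetwork, np.ndarray]:
    """Three normalized layers sharing one planted core; returns the truth.

    ``noise`` is the SD of a multiplicative jitter ``(1 + noise * eps)`` on
    each edge (clipped to stay positive), so ``noise=0`` gives the exact
    block weights.
    """
    core = np.asarray(sorted(set(int(i) for i in core_set)), dtype=int)
    if core.size == 0:
        raise ValueError("core_set must be nonempty")
    if core.size >= n_nodes or core.min() < 0 or core.max() >= n_nodes:
        raise ValueError("core_set must be a proper subset of node indices")
    w_cc, w_cp, w_pp = weight_means
    if not (w_cc > w_cp > w_pp > 0):
        raise ValueError("weight means must satisfy w_cc > w_cp > w_pp > 0")
    rng = np.random.default_rng(seed)
    core_mask = np.zeros(n_nodes, dtype=bool)
    core_mask[core] = True
    labels = list(node_labels) if node_labels else [f"node{i:03d}" for i in range(n_nodes)]

    def draw(r, means):
        jitter = 1.0 + noise * r.standard_normal(means.shape)
        return means * np.clip(jitter, 0.05, None)

    kinds = ("MC", "SC", "FC")[:n_layers]
    layers = []
    for kind in kinds:
        w = _block_matrix(rng, n_nodes, core_mask, (w_cc, w_cp, w_pp), draw)
        layers.append(svd_normalize(ConnectivityLayer(kind, w, labels)))
    return MultiplexNetwork(layers=tuple(layers), node_labels=labels), core


def simulate_cohort(
    n_hc: int,
    n_ms: int,
    n_nodes: int = 114,
    n_core: int = 20,
    phenotype_mix: Mapping[str, float] | None = None,
    site_count: int = 1,
    params: Mapping | None = None,
    seed=None,
) -> tuple[CohortData, SyntheticTruth]:
    """Generate a full synthetic cohort plus its ground truth.

    Controls carry ``delta = 0``; patients draw ``delta`` from a clipped
    normal around their phenotype's mean.  The targeted attack hits SC and
    FC edges multiplicatively and core-node volumes via the atrophy term, so
    all three layers carry (correlated) disease signal.
    """
    if n_core >= n_nodes:
        raise ValueError(f"n_core ({n_core}) must be smaller than n_nodes ({n_nodes})")
    mix = dict(phenotype_mix) if phenotype_mix else dict(DEFAULT_PHENOTYPE_MIX)
    unknown = set(mix) - set(_PHENOTYPES)
    if unknown:
        raise ValueError(f"unknown phenotypes in mix: {sorted(unknown)}")
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"phenotype_mix must sum to 1, got {total}")
    p = _merge_params(params)
    rng = np.random.default_rng(seed)

    parcellation = make_parcellation(n_nodes)
    labels = parcellation.node_labels
    core_idx = np.sort(rng.choice(n_nodes, size=n_core, replace=False))
    affinity = np.zeros(n_nodes)
    affinity[core_idx] = 1.0
    core_mask = affinity > 0

    n = n_hc + n_ms
    ids = [f"sub{k:04d}" for k in range(n)]
    group = np.array(["HC"] * n_hc + ["MS"] * n_ms)
    phen_names = [ph for ph in _PHENOTYPES if mix.get(ph, 0) > 0]
    phen_probs = np.array([mix[ph] for ph in phen_names])
    phenotype = np.array(
        ["NA"] * n_hc + list(rng.choice(phen_names, size=n_ms, p=phen_probs))
    )
    sites = np.array([f"site{1 + rng.integers(site_count):02d}" for _ in range(n)])

    age = np.clip(rng.normal(41.0, 12.0, n), 18.0, 75.0)
    sex = rng.choice(["F", "M"], size=n, p=[0.62, 0.38])
    sex01 = (sex == "M").astype(float)
    tiv = rng.normal(1450.0, 120.0, n)

    d_by_ph = p["delta_by_phenotype"]
    delta = np.zeros(n)
    for k in range(n_hc, n):
        delta[k] = np.clip(
            rng.normal(d_by_ph[phenotype[k]], p["delta_sd"]), 0.0, 1.0
        )

    # --- regional volumes: linear in covariates + noise, atrophy on core nodes
    base = rng.uniform(*p["volume_base_range"], size=n_nodes)
    sl = p["covariate_slopes"]
    vols = (
        base[None, :]
        + sl["age"] * (age - 41.0)[:, None]
        + sl["sex"] * sex01[:, None]
        + sl["tiv"] * (tiv - 1450.0)[:, None]
        + rng.normal(0.0, p["volume_noise_sd"], (n, n_nodes))
    )
    vols *= 1.0 - p["atrophy_scale"] * delta[:, None] * affinity[None, :]
    vols = np.clip(vols, 0.1, None)

    # --- SC (raw streamline weights) and FC (correlation-like) matrices
    shape = p["sc_gamma_shape"]

    def draw_sc(r, means):
        return r.gamma(shape, means / shape)

    def draw_fc(r, means):
        return np.clip(means + r.normal(0.0, p["fc_corr_noise"], means.shape), -0.97, 0.97)

    sc, fc = {}, {}
    for k, sid in enumerate(ids):
        raw_sc = _block_matrix(rng, n_nodes, core_mask, p["sc_weight_means"], draw_sc)
        raw_fc = _block_matrix(rng, n_nodes, core_mask, p["fc_corr_means"], draw_fc)
        if delta[k] > 0:
            raw_sc = apply_targeted_attack(raw_sc, affinity, delta[k])
            raw_fc = apply_targeted_attack(raw_fc, affinity, delta[k])
        sc[sid] = raw_sc
        fc[sid] = raw_fc

    # --- clinical scores, monotone in delta
    em, sm, bm, tm = p["edss_model"], p["sdmt_model"], p["bpf_model"], p["tlv_model"]
    edss = np.round(
        np.clip(em["intercept"] + em["slope"] * delta + rng.normal(0, em["noise_sd"], n),
                0.0, 10.0) * 2.0
    ) / 2.0
    sdmt = sm["slope"] * delta + rng.normal(0, sm["noise_sd"], n)
    bpf = np.clip(
        bm["intercept"] + bm["delta_slope"] * delta + bm["age_slope"] * (age - 41.0)
        + rng.normal(0, bm["noise_sd"], n), 0.55, 0.95,
    )
    tlv = rng.gamma(tm["shape"], (tm["base_mean"] + tm["delta_gain"] * delta) / tm["shape"])

    hc = group == "HC"
    table = pd.DataFrame(
        {
            "subject_id": ids,
            "group": group,
            "phenotype": phenotype,
            "site": sites,
            "age": age,
            "sex": sex,
            "tiv": tiv,
            "edss": np.where(hc, np.nan, edss),
            "sdmt_z": np.where(hc, np.nan, sdmt),
            "bpf": bpf,
            "tlv": np.where(hc, np.nan, tlv),
        }
    )

    # --- site effects, applied last (location + scale)
    site_offsets: dict[str, dict[str, float]] = {}
    if site_count > 1:
        for s in sorted(set(sites)):
            site_offsets[s] = {
                "volume_shift": float(rng.normal(0.0, p["site_volume_shift_sd"])),
                "volume_scale": float(
                    np.clip(1.0 + rng.normal(0.0, p["site_volume_scale_sd"]), 0.7, 1.3)
                ),
                "edge_scale": float(
                    np.clip(1.0 + rng.normal(0.0, p["site_edge_scale_sd"]), 0.5, 1.5)
                ),
                "fc_shift": float(rng.normal(0.0, p["site_fc_shift_sd"])),
            }
        for k, sid in enumerate(ids):
            off = site_offsets[sites[k]]
            vols[k] = vols[k] * off["volume_scale"] + off["volume_shift"]
            sc[sid] = sc[sid] * off["edge_scale"]
            shifted = np.clip(fc[sid] + off["fc_shift"], -0.97, 0.97)
            np.fill_diagonal(shifted, 0.0)
            fc[sid] = shifted

    volumes = pd.DataFrame(vols, index=ids, columns=labels)
    validate_cohort_table(table)
    cohort = CohortData(
        cohort=table, volumes=volumes, sc=sc, fc=fc, parcellation=parcellation
    )
    truth = SyntheticTruth(
        core_nodes=[labels[i] for i in core_idx],
        core_indices=core_idx,
        affinity=affinity,
        attack_strength={sid: float(delta[k]) for k, sid in enumerate(ids)},
        site_offsets=site_offsets,
        covariate_slopes=dict(sl),
        weight_means={"sc": tuple(p["sc_weight_means"]), "fc": tuple(p["fc_corr_means"])},
    )
    return cohort, truth
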