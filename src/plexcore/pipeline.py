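"""End-to-end orchestration: simulate/load -> build layers -> harmonize ->
coreness -> kappa -> group statistics -> prediction -> write results.

Every stochastic stage draws its seed deterministically from the single
top-level ``seed`` via a SeedSequence, so re-running a config reproduces
all numeric outputs exactly.
"""

from __future__ import annotations

import logging
from copy import deepcopy
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .core import CorenessDisruption, CorenessExtractor, DensityGrid, LayerCoefficients
from .harmonize import ComBatHarmonizer, clamp_nonnegative
from .layers import (assemble_multiplex, build_mc_layer, svd_normalize,
                     transform_fc, transform_sc, zscore_volumes)
from .simulate import simulate_cohort
from .stats import (adjust_confounders, anova_tukey, dichotomize_clinical,
                    hedges_g, nodal_comparison, permutation_ttest)
from .predict import build_feature_tables, fit_bagged_trees

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "validate_config", "build_multiplexes", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": None,
    "simulate": {
        "n_hc": 60,
        "n_ms": 120,
        "n_nodes": 114,
        "n_core": 20,
        "site_count": 1,
        "phenotype_mix": None,
        "params": {},
    },
    "inputs": {
        "cohort": None,
        "volumes": None,
        "matrix_dir": None,
        "parcellation": None,
    },
    "grid": {"start": 0.01, "stop": 1.0, "step": 0.01},
    "coefficients": [0.5, 0.5, 0.5],
    "harmonize": {"enabled": "auto", "use_eb": True},
    "subset": {"bpf_z_min": None},
    "stats": {"n_perm": 10000, "n_boot": 5000, "q": 0.05},
    "predict": {
        "enabled": True,
        "tasks": ["status", "disability", "ips"],
        "search_budget": 6,
    },
}


def validate_config(config: dict) -> dict:
    """Merge a user config over the defaults; unknown keys are hard errors."""

    def merge(defaults, user, path=""):
        out = deepcopy(defaults)
        for key, val in (user or {}).items():
            if key not in defaults:
                raise ValueError(
                    f"invalid config key {path + key!r}; "
                    f"valid keys: {sorted(defaults)}"
                )
            if isinstance(defaults[key], dict) and key != "params" and isinstance(val, dict):
                out[key] = merge(defaults[key], val, path + key + ".")
            else:
                out[key] = deepcopy(val)
        return out

    return merge(DEFAULT_CONFIG, config or {})


def _child_seeds(seed, n):
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31 - 1)]


# ---------------------------------------------------------------------------
# layer building
# ---------------------------------------------------------------------------

def _edge_vectors(mats: dict[str, np.ndarray], ids, n):
    iu, ju = np.triu_indices(n, k=1)
    return np.vstack([mats[sid][iu, ju] for sid in ids]), (iu, ju)


def _edges_to_matrices(edges: np.ndarray, ids, n, tri):
    iu, ju = tri
    out = {}
    for row, sid in zip(edges, ids):
        m = np.zeros((n, n))
        m[iu, ju] = row
        m += m.T
        out[sid] = m
    return out


def build_multiplexes(data: io.CohortData, harmonize: str | bool = "auto",
                      use_eb: bool = True):
    """Transform raw inputs into per-subject normalized multiplex networks.

    Order of operations: ComBat on raw volumes, then HC-anchored z-scoring
    and the MC edge formula; log10(1+w) on SC and |atanh(r)| on FC, ComBat
    on the transformed edge vectors, negative weights clamped to zero; every
    layer divided by its largest singular value; layers stacked.

    Returns ``(multiplexes: dict id -> MultiplexNetwork, volume_z)``.
    """
    ids = data.subject_ids
    n = data.parcellation.n_nodes
    labels = data.parcellation.node_labels
    tab = data.cohort
    sites = tab["site"].to_numpy()
    n_sites = len(set(sites))
    do_harm = (n_sites > 1) if harmonize == "auto" else bool(harmonize)
    bio = np.column_stack([
        tab["age"].to_numpy(float),
        (tab["sex"] == "M").to_numpy(float),
        (tab["group"] == "MS").to_numpy(float),
    ])

    volumes = data.volumes.to_numpy(float)
    if do_harm:
        logger.info("harmonizing volumes across %d sites", n_sites)
        volumes = ComBatHarmonizer(use_eb=use_eb).fit_transform(
            volumes, site=sites, covariates=bio
        )

    covs = np.column_stack([
        tab["age"].to_numpy(float),
        (tab["sex"] == "M").to_numpy(float),
        tab["tiv"].to_numpy(float),
    ])
    vz = zscore_volumes(volumes, covs, data.hc_mask)

    sc_t = {sid: transform_sc(data.sc[sid], labels).weights for sid in ids}
    fc_t = {sid: transform_fc(data.fc[sid], labels).weights for sid in ids}
    if do_harm:
        for name, store in (("SC", sc_t), ("FC", fc_t)):
            edges, tri = _edge_vectors(store, ids, n)
            edges = ComBatHarmonizer(use_eb=use_eb).fit_transform(
                edges, site=sites, covariates=bio
            )
            edges = clamp_nonnegative(edges)
            store.update(_edges_to_matrices(edges, ids, n, tri))
            logger.info("harmonized %s edge weights", name)

    multiplexes = {}
    for k, sid in enumerate(ids):
        mc = svd_normalize(build_mc_layer(vz.z[k], labels))
        sc = svd_normalize(_relabel(sc_t[sid], "SC", labels))
        fc = svd_normalize(_relabel(fc_t[sid], "FC", labels))
        multiplexes[sid] = assemble_multiplex(mc, sc, fc)
    return multiplexes, vz


def _relabel(weights, kind, labels):
    from .layers import ConnectivityLayer
    return ConnectivityLayer(kind, weights, list(labels))


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: dict | None = None) -> dict:
    """Run the whole analysis per the config; returns the summary report."""
    cfg = validate_config(config)
    seeds = _child_seeds(cfg["seed"], 8)
    report: dict = {"config_seed": cfg["seed"]}

    # -- inputs -------------------------------------------------------------
    inp = cfg["inputs"]
    if inp["cohort"] is not None:
        logger.info("loading cohort from %s", inp["cohort"])
        data = io.read_cohort(
            inp["cohort"], inp["volumes"], inp["matrix_dir"], inp["parcellation"]
        )
        truth = None
    else:
        sim = cfg["simulate"]
        logger.info("simulating cohort: %s", sim)
        data, truth = simulate_cohort(
            n_hc=sim["n_hc"], n_ms=sim["n_ms"], n_nodes=sim["n_nodes"],
            n_core=sim["n_core"], phenotype_mix=sim["phenotype_mix"],
            site_count=sim["site_count"], params=sim["params"], seed=seeds[0],
        )
    ids = data.subject_ids
    tab = data.cohort
    hc_mask = data.hc_mask
    report["n_hc"] = int(hc_mask.sum())
    report["n_ms"] = int((~hc_mask).sum())

    # -- layers -------------------------------------------------------------
    harm = cfg["harmonize"]
    multiplexes, _ = build_multiplexes(
        data, harmonize=harm["enabled"], use_eb=harm["use_eb"]
    )

    # -- coreness -----------------------------------------------------------
    g = cfg["grid"]
    grid = DensityGrid.from_range(g["start"], g["stop"], g["step"])
    coeffs = LayerCoefficients(np.asarray(cfg["coefficients"], float))
    logger.info("coreness sweep: %d densities, coefficients %s",
                len(grid), list(coeffs.c))
    mx_list = [multiplexes[sid] for sid in ids]
    coreness_by_domain = {}
    for domain in ("multiplex", "MC", "SC", "FC"):
        ext = CorenessExtractor(
            grid=grid, coefficients=coeffs if domain == "multiplex" else None,
            domain=domain,
        )
        coreness_by_domain[domain] = ext.transform(mx_list)
    coreness_table = pd.DataFrame(
        coreness_by_domain["multiplex"], index=ids,
        columns=data.parcellation.node_labels,
    )

    # -- kappa --------------------------------------------------------------
    kappa_cols = {}
    for domain, mat in coreness_by_domain.items():
        disruptor = CorenessDisruption().fit(mat[hc_mask])
        kappa_cols[domain] = disruptor.transform(mat)
    kappa_table = pd.DataFrame(kappa_cols, index=ids)

    # -- statistics ---------------------------------------------------------
    st = cfg["stats"]
    covs = np.column_stack(
        [tab["age"].to_numpy(float), (tab["sex"] == "M").to_numpy(float)]
    )
    subset_mask = np.ones(len(ids), dtype=bool)
    if cfg["subset"]["bpf_z_min"] is not None:
        bpf_z = adjust_confounders(
            tab["bpf"].to_numpy(float), covs, hc_mask
        ).z
        subset_mask = bpf_z > cfg["subset"]["bpf_z_min"]
        logger.info("subset filter bpf_z > %s keeps %d/%d subjects",
                    cfg["subset"]["bpf_z_min"], int(subset_mask.sum()), len(ids))
    stats_report = _run_stats(
        kappa_table, coreness_table, tab, covs, hc_mask, subset_mask,
        n_perm=st["n_perm"], n_boot=st["n_boot"], q=st["q"], seed=seeds[1],
    )
    report["stats"] = stats_report

    # -- prediction ---------------------------------------------------------
    pred_report = {}
    if cfg["predict"]["enabled"]:
        for i, task in enumerate(cfg["predict"]["tasks"]):
            try:
                feats, labels = build_feature_tables(kappa_table, tab, task)
                _, rep = fit_bagged_trees(
                    feats.to_numpy(float), labels.to_numpy(),
                    search_budget=cfg["predict"]["search_budget"],
                    seed=seeds[2 + i], task=task,
                    feature_names=list(feats.columns),
                )
                pred_report[task] = rep.__dict__
            except ValueError as exc:
                logger.warning("prediction task %s skipped: %s", task, exc)
                pred_report[task] = {"skipped": str(exc)}
    report["prediction"] = pred_report

    # -- outputs ------------------------------------------------------------
    if cfg["out_dir"]:
        paths = io.write_results(
            cfg["out_dir"], coreness_table, kappa_table, stats_report, pred_report
        )
        report["outputs"] = {k: str(v) for k, v in paths.items()}
        if truth is not None:
            import json
            tpath = Path(cfg["out_dir"]) / "truth.json"
            with open(tpath, "w") as fh:
                json.dump(io._jsonable({
                    "core_nodes": truth.core_nodes,
                    "attack_strength": truth.attack_strength,
                    "site_offsets": truth.site_offsets,
                }), fh, indent=2, sort_keys=True)
            report["outputs"]["truth"] = str(tpath)
    report["kappa_table"] = kappa_table
    report["coreness_table"] = coreness_table
    return report


def _adjust_matrix_columns(values: np.ndarray, covs, hc_mask):
    """Column-wise HC-anchored adjustment; zero-HC-variance columns are
    centered on the HC mean but left unscaled (logged)."""
    X = np.atleast_2d(np.asarray(values, float))
    hc = np.asarray(hc_mask, bool)
    sd = X[hc].std(axis=0, ddof=1)
    ok = sd > 0
    out = np.empty_like(X)
    if ok.any():
        out[:, ok] = adjust_confounders(X[:, ok], covs, hc).z
    if (~ok).any():
        logger.info("%d node(s) constant over HC: centered, not standardized",
                    int((~ok).sum()))
        out[:, ~ok] = X[:, ~ok] - X[hc][:, ~ok].mean(axis=0)
    return out


def _run_stats(kappa_table, coreness_table, tab, covs, hc_mask, subset_mask,
               *, n_perm, n_boot, q, seed):
    seeds = _child_seeds(seed, 12)
    hc = hc_mask & subset_mask
    ms = (~hc_mask) & subset_mask
    out: dict = {"n_hc_used": int(hc.sum()), "n_ms_used": int(ms.sum())}

    # global kappa comparisons per domain, on confounder-adjusted z-scores
    sub_tab = tab.loc[subset_mask].reset_index(drop=True)
    is_hc = (sub_tab["group"] == "HC").to_numpy()
    domains = list(kappa_table.columns)
    kz = {}
    for dom in domains:
        kz[dom] = adjust_confounders(
            kappa_table[dom].to_numpy(float)[subset_mask], covs[subset_mask],
            is_hc,
        ).z
    group_section = {}
    for i, dom in enumerate(domains):
        z = kz[dom]
        t, p = permutation_ttest(z[~is_hc], z[is_hc], n_perm=n_perm,
                                 seed=seeds[i])
        gval, (lo, hi) = hedges_g(z[~is_hc], z[is_hc], n_boot=n_boot,
                                  seed=seeds[i])
        raw = kappa_table[dom].to_numpy(float)[subset_mask]
        group_section[dom] = {
            "mean_kappa_ms": float(raw[~is_hc].mean()),
            "mean_kappa_hc": float(raw[is_hc].mean()),
            "t": t, "p": p, "hedges_g": gval, "g_ci": [lo, hi],
        }
    out["group_kappa"] = group_section

    # nodal coreness MS vs HC with BH-FDR
    cz = _adjust_matrix_columns(
        coreness_table.to_numpy(float)[subset_mask], covs[subset_mask],
        is_hc,
    )
    nodal = nodal_comparison(cz, np.where(is_hc, "HC", "MS"), n_perm=n_perm,
                             q=q, seed=seeds[4])
    nodal.index = coreness_table.columns
    out["nodal"] = {
        "n_significant": int(nodal["significant"].sum()),
        "n_nodes": int(len(nodal)),
        "table": nodal.reset_index().rename(columns={"index": "node"})
                      .to_dict(orient="list"),
    }

    # phenotype ANOVA on adjusted multiplex kappa (MS only)
    phen = sub_tab.loc[~is_hc, "phenotype"].to_numpy()
    kz_ms = kz["multiplex"][~is_hc]
    present = [ph for ph in ("CIS", "RRMS", "SPMS", "PPMS")
               if (phen == ph).sum() >= 2]
    if len(present) >= 2:
        mask = np.isin(phen, present)
        F, p, pairwise = anova_tukey(kz_ms[mask], phen[mask])
        out["phenotype_anova"] = {
            "F": F, "p": p,
            "group_means": {ph: float(kz_ms[phen == ph].mean()) for ph in present},
            "tukey": pairwise.to_dict(orient="list"),
        }

    # clinical dichotomies on adjusted multiplex kappa (MS only)
    dich = dichotomize_clinical(sub_tab.loc[~is_hc])
    for name, col in (("edss", "high_disability"), ("ips", "ips_impaired")):
        lab = dich[col]
        valid = lab.notna().to_numpy()
        if valid.sum() >= 4 and lab[valid].nunique() == 2:
            hi = kz_ms[valid & lab.fillna(False).to_numpy()]
            lo_grp = kz_ms[valid & ~lab.fillna(True).to_numpy()]
            if hi.size >= 2 and lo_grp.size >= 2:
                t, p = permutation_ttest(lo_grp, hi, n_perm=n_perm,
                                         seed=seeds[6])
                gval, (glo, ghi) = hedges_g(lo_grp, hi, n_boot=n_boot,
                                            seed=seeds[7])
                out[f"{name}_comparison"] = {
                    "t": t, "p": p, "hedges_g": gval, "g_ci": [glo, ghi],
                    "n_impaired": int(hi.size), "n_preserved": int(lo_grp.size),
                }
    return out
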