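"""End-to-end orchestration: simulate → decompose → score → match → FNC → stats.

The pipeline mirrors a complete structural-covariance / functional-network
study on a synthetic cohort with planted ground truth:

1. build a phantom source atlas and simulate smoothed structural maps for
   patients and controls (cingulate loading covariance strong in controls,
   weak in patients, plus a mean cingulate deficit in patients);
2. group spatial ICA (ICASSO-stabilized Infomax) over all subjects →
   per-subject network integrity scores → covariate-adjusted group tests
   with BH-FDR over the signal networks;
3. per-group ICA with Dice matching of the group component sets;
4. binary cingulate templates from the control decomposition (z > 3);
5. functional group ICA on BOLD-like series, per-subject dual regression,
   one-sample t-maps, GOF selection of the anterior and posterior
   functional components;
6. per-subject FNC between the two selected components, group comparison,
   partial correlation with integrity, and the longitudinal paired
   contrast;
7. demographic tables with summary-statistic tests.

Every stage draws its randomness from a child seed of ``cfg.seed``, so a
fixed config reproduces every numeric output exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .cohort import (
    CLINICAL_SPEC_HC,
    CLINICAL_SPEC_PD,
    CLINICAL_SPEC_PD_FOLLOWUP,
    CLINICAL_SPEC_PD_SUBGROUP,
    DEFAULT_RHO_FUNC,
    simulate_clinical_table,
    simulate_functional_subject,
    simulate_structural_cohort,
)
from .config import PipelineConfig, validate_config
from .fnc import fnc_value
from .gstats import (
    GroupStatResult,
    adjusted_two_sample_test,
    bh_fdr,
    paired_test,
    partial_correlation,
    summary_anova,
    summary_ttest,
)
from .ica import ComponentSet, decompose_structural, dual_regression, pca_reduce, \
    threshold_map, zscore_maps, fix_sign_and_order, flag_artifact_components, \
    _loadings_by_regression
from .phantom import SourceAtlas, make_phantom_sources
from .preprocess import drop_initial_volumes, smooth_map
from .scores import gof, integrity_table, match_component_sets, one_sample_tmap

__all__ = ["ResultBundle", "run_pipeline"]

#: Strength of the planted subject-level coupling between cingulate
#: structural integrity and functional connectivity (FNC rises as the
#: structural loading falls), producing the negative integrity–FNC
#: partial correlation in patients.
FNC_COUPLING = 0.12


@dataclass
class ResultBundle:
    """Everything a full pipeline run produces."""

    config: PipelineConfig
    atlas: SourceAtlas
    structural_all: ComponentSet
    structural_hc: ComponentSet
    structural_pd: ComponentSet
    functional: ComponentSet
    subjects: pd.DataFrame
    integrity: pd.DataFrame
    integrity_stats: pd.DataFrame
    dice_hc: list
    dice_pd: list
    templates: dict
    gof_tables: dict
    selected: dict
    fnc: pd.DataFrame
    fnc_stats: dict
    clinical_stats: pd.DataFrame
    matched_components: dict
    seed_log: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        h = self.config.config_hash()
        meta = {"config": self.config.to_dict(), "config_hash": h,
                "seeds": self.seed_log}
        cio.save_json(out / "run_metadata.json", meta)
        for name, df in [
            ("subjects.tsv", self.subjects),
            ("integrity.tsv", self.integrity),
            ("integrity_stats.tsv", self.integrity_stats),
            ("fnc.tsv", self.fnc),
            ("clinical_stats.tsv", self.clinical_stats),
        ]:
            df2 = df.copy()
            df2["config_hash"] = h
            cio.save_table(out / name, df2)
        cio.save_json(out / "fnc_stats.json", self.fnc_stats)
        cio.save_json(out / "dice_matching.json",
                      {"hc": self.dice_hc, "pd": self.dice_pd,
                       "matched_components": self.matched_components,
                       "config_hash": h})
        cio.save_json(out / "selected_components.json",
                      {**self.selected, "config_hash": h})
        vox = self.atlas.voxel_mm
        cio.save_maps_4d(out / "structural_components.nii.gz",
                         self.structural_all.maps, self.structural_all.mask, vox)
        cio.save_maps_4d(out / "functional_components.nii.gz",
                         self.functional.maps, self.functional.mask, vox)
        cio.save_volume(out / "brain_mask.nii.gz",
                        self.atlas.brain_mask.astype(float), vox)
        cio.save_json(out / "component_labels.json", {
            "structural": self.structural_all.labels,
            "functional": self.functional.labels,
            "structural_iq": self.structural_all.iq,
            "functional_iq": self.functional.iq,
        })


def _child_seeds(seed: int, names) -> dict:
    rng = np.random.default_rng(seed)
    return {name: int(s) for name, s in
            zip(names, rng.integers(0, 2**31 - 1, size=len(names)))}


def match_to_sources(cs: ComponentSet, atlas: SourceAtlas) -> dict:
    """Map each atlas role to its best-matching component (by |spatial r|)."""
    F = atlas.flat_sources()
    # component maps live on the analysis mask; atlas sources on the full grid
    sel = cs.mask.ravel()
    Fm = F[:, sel]
    C = np.abs(np.corrcoef(np.vstack([Fm, cs.maps]))[:atlas.k_true, atlas.k_true:])
    return {
        role: {"component": int(np.argmax(C[j])), "r": float(C[j].max())}
        for j, role in enumerate(atlas.roles)
    }


def integrity_group_stats(integrity: pd.DataFrame, cs: ComponentSet,
                           alpha: float) -> pd.DataFrame:
    """Adjusted PD-vs-HC test per signal network, BH-FDR over the family."""
    sex_num = (integrity["sex"] == "M").astype(float)
    cov = np.column_stack([integrity["age"].to_numpy(), sex_num.to_numpy()])
    rows = []
    for j in cs.signal_indices():
        name = f"IC{j + 1}"
        res = adjusted_two_sample_test(
            integrity[name].to_numpy(), integrity["group"].to_numpy(), cov
        )
        # labels sort as [HC, PD], so the effect is already PD − HC
        rows.append({"network": name, "component": int(j),
                     "effect_pd_minus_hc": res.effect,
                     "t": res.t, "df": res.df, "p": res.p})
    out = pd.DataFrame(rows)
    qvals, rej = bh_fdr(out["p"].to_numpy(), alpha)
    out["q"] = qvals
    out["significant"] = rej
    out["family_size"] = len(out)
    return out


def run_pipeline(
    config=None,
    out_dir=None,
    *,
    n_pd: int = 100,
    n_hc: int = 70,
    n_followup: int = 51,
    k_true: int = 6,
    grid_shape=(32, 40, 32),
    n_group_ica_subjects: int = 30,
    rho_func=None,
) -> ResultBundle:
    """Run the complete analysis on a freshly simulated cohort.

    ``config`` may be a YAML path, dict, or :class:`PipelineConfig`.  Cohort
    sizes default to the study conditions (100 patients, 70 controls, 51
    longitudinal patients).  Returns a :class:`ResultBundle`; when
    ``out_dir`` is given all tables/maps are also written there.
    """
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    rho_func = dict(DEFAULT_RHO_FUNC if rho_func is None else rho_func)
    seeds = _child_seeds(cfg.seed, [
        "atlas", "structural", "clinical", "functional", "group_ica",
    ])

    # ---- stage 1: phantom + structural cohort -------------------------------
    atlas = make_phantom_sources(grid_shape, k_true, seed=seeds["atlas"])
    stack, truth = simulate_structural_cohort(
        atlas, n_pd=n_pd, n_hc=n_hc, seed=seeds["structural"]
    )
    stack = np.stack([smooth_map(v, cfg.fwhm_mm, atlas.voxel_mm) for v in stack])

    subjects = simulate_clinical_table({
        "PD": {"n": n_pd, "group": "PD", "male_frac": 0.55, **CLINICAL_SPEC_PD},
        "HC": {"n": n_hc, "group": "HC", "male_frac": 30 / 70, **CLINICAL_SPEC_HC},
    }, seed=seeds["clinical"])

    # ---- stage 2: all-subject structural ICA + integrity stats --------------
    cs_all, _ = decompose_structural(stack, cfg, brain_mask=atlas.brain_mask)
    meta = subjects[["id", "group", "visit", "sex", "age"]]
    X_all = stack.reshape(stack.shape[0], -1)[:, cs_all.mask.ravel()]
    integrity = integrity_table(X_all, cs_all.maps, meta=meta)
    integrity_stats = integrity_group_stats(integrity, cs_all, cfg.fdr_alpha)

    # ---- stage 3: per-group ICA + Dice matching -----------------------------
    cs_pd, _ = decompose_structural(stack[:n_pd], cfg, brain_mask=atlas.brain_mask)
    cs_hc, _ = decompose_structural(stack[n_pd:], cfg, brain_mask=atlas.brain_mask)
    dice_hc = match_component_sets(cs_all.maps, cs_hc.maps, cfg.z_threshold)
    dice_pd = match_component_sets(cs_all.maps, cs_pd.maps, cfg.z_threshold)

    # ---- stage 4: cingulate templates from the control decomposition --------
    match_hc = match_to_sources(cs_hc, atlas)
    match_all = match_to_sources(cs_all, atlas)
    i_ant_hc = match_hc["anterior_cingulate"]["component"]
    i_post_hc = match_hc["posterior_cingulate"]["component"]
    templates = {
        "anterior": threshold_map(cs_hc.maps[i_ant_hc], cfg.z_threshold),
        "posterior": threshold_map(cs_hc.maps[i_post_hc], cfg.z_threshold),
    }

    # ---- stage 5: functional cohort + group ICA + dual regression -----------
    # subject-visit design: PD baseline, PD follow-up subset, HC baseline
    fmeta = _functional_design(subjects, n_pd, n_hc, n_followup)
    # couple each subject-visit's planted rho to its structural integrity
    i_ant_all = match_all["anterior_cingulate"]["component"]
    ant_beta = integrity[f"IC{i_ant_all + 1}"].to_numpy()
    z_ant = (ant_beta - ant_beta.mean()) / ant_beta.std()
    base = np.array([rho_func[(g, v)] for g, v in zip(fmeta["group"], fmeta["visit"])])
    z_by_row = z_ant[fmeta["subject_index"].to_numpy()]
    rhos = np.clip(base - FNC_COUPLING * z_by_row, -0.9, 0.9)
    fmeta = fmeta.assign(planted_rho=rhos)

    froot = np.random.default_rng(seeds["functional"])
    f_seeds = froot.integers(0, 2**31 - 1, size=len(fmeta))

    def _gen(i):
        series, _ = simulate_functional_subject(
            atlas, float(fmeta["planted_rho"].iloc[i]),
            n_volumes=cfg.n_volumes, tr_s=cfg.tr_s, seed=int(f_seeds[i]),
        )
        flat = series.reshape(series.shape[0], -1)
        return drop_initial_volumes(flat, cfg.drop_volumes)

    # group ICA on a subject subset (memory-bounded); dual regression on all
    rng_sub = np.random.default_rng(seeds["group_ica"])
    subset = rng_sub.choice(len(fmeta), size=min(n_group_ica_subjects, len(fmeta)),
                            replace=False)
    k = cfg.n_components
    reduced = [pca_reduce(_gen(int(i)), min(int(np.ceil(1.5 * k)),
                                            cfg.n_volumes - cfg.drop_volumes)).reduced
               for i in subset]
    concat = np.vstack(reduced)
    del reduced
    Xw_group = pca_reduce(concat, k)
    from .icasso import run_icasso
    fres = run_icasso(Xw_group, k=k, n_runs=cfg.n_icasso_runs, seed=cfg.seed)
    fmaps, _ = fix_sign_and_order(fres.centrotypes, None)
    betas = _loadings_by_regression(concat, zscore_maps(fmaps))
    order = np.argsort(-np.linalg.norm(betas, axis=0))
    fmaps = zscore_maps(fmaps[order])
    del concat
    full_mask = np.ones(atlas.grid_shape, dtype=bool)
    flabels = flag_artifact_components(fmaps, full_mask, atlas.brain_mask,
                                       cfg.z_threshold)
    functional = ComponentSet(maps=fmaps, loadings=betas[:, order], mask=full_mask,
                              labels=flabels, iq=fres.iq_per_centrotype()[order],
                              converged=all(fres.converged))

    # one pass over all subject-visits: dual regression → GOF rows, t-map
    # accumulators, and the conditioned time courses of every component
    gof_rows = {"anterior": [], "posterior": []}
    tcs_store = []
    tmap_acc = {}
    for i in range(len(fmeta)):
        series = _gen(i)
        tcs, smaps = dual_regression(series, fmaps)
        tcs_store.append(tcs)
        g = fmeta["group"].iloc[i]
        acc = tmap_acc.setdefault(g, [np.zeros_like(smaps), np.zeros_like(smaps), 0])
        acc[0] += smaps
        acc[1] += smaps**2
        acc[2] += 1
        for tname, tmpl in templates.items():
            row = [gof(smaps[j], tmpl) if flabels[j] == "signal" else np.nan
                   for j in range(k)]
            gof_rows[tname].append(row)

    gof_tables = {
        t: pd.DataFrame(rows, columns=[f"IC{j + 1}" for j in range(k)])
        for t, rows in gof_rows.items()
    }
    signal_idx = [j for j in range(k) if flabels[j] == "signal"]
    if not signal_idx:
        raise RuntimeError("functional decomposition produced no signal components")
    selected = {}
    for tname, table in gof_tables.items():
        mean_gof = table.mean(axis=0).to_numpy()
        mean_gof[[j for j in range(k) if j not in signal_idx]] = -np.inf
        selected[tname] = int(np.argmax(mean_gof))
    if selected["anterior"] == selected["posterior"]:
        # degenerate selection: force distinct components (second-best posterior)
        mg = gof_tables["posterior"].mean(axis=0).to_numpy()
        mg[[j for j in range(k) if j not in signal_idx]] = -np.inf
        mg[selected["anterior"]] = -np.inf
        selected["posterior"] = int(np.argmax(mg))

    # group one-sample t-maps of the selected components (per group)
    tmaps = {}
    for g, (s1, s2, n) in tmap_acc.items():
        mean = s1 / n
        sd = np.sqrt(np.clip((s2 - n * mean**2) / (n - 1), 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            tm = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
        tmaps[g] = tm

    # ---- stage 6: FNC + group stats ----------------------------------------
    ja, jp = selected["anterior"], selected["posterior"]
    fnc_rows = []
    for i in range(len(fmeta)):
        r = fnc_value(tcs_store[i][:, ja], tcs_store[i][:, jp], cfg)
        fnc_rows.append({**{c: fmeta[c].iloc[i] for c in
                            ("id", "group", "visit", "sex", "age", "subject_index",
                             "planted_rho")},
                         "r": r, "fisher_z": float(np.arctanh(r))})
    fnc_df = pd.DataFrame(fnc_rows)

    fnc_stats = _fnc_group_stats(fnc_df, integrity, f"IC{i_ant_all + 1}")

    # ---- stage 7: demographic-table statistics ------------------------------
    clinical_stats = table_statistics()

    bundle = ResultBundle(
        config=cfg, atlas=atlas, structural_all=cs_all, structural_hc=cs_hc,
        structural_pd=cs_pd, functional=functional, subjects=subjects,
        integrity=integrity, integrity_stats=integrity_stats,
        dice_hc=dice_hc, dice_pd=dice_pd, templates=templates,
        gof_tables=gof_tables, selected=selected, fnc=fnc_df,
        fnc_stats=fnc_stats, clinical_stats=clinical_stats,
        matched_components={"hc": match_hc, "all": match_all},
        seed_log=seeds,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def _functional_design(subjects: pd.DataFrame, n_pd: int, n_hc: int,
                       n_followup: int) -> pd.DataFrame:
    """Subject-visit rows: all baselines plus the PD longitudinal subset."""
    rows = []
    for idx in range(n_pd + n_hc):
        s = subjects.iloc[idx]
        rows.append({"id": s["id"], "group": s["group"], "visit": "baseline",
                     "sex": s["sex"], "age": s["age"], "subject_index": idx})
    for idx in range(n_followup):  # first n_followup patients return
        s = subjects.iloc[idx]
        rows.append({"id": s["id"], "group": "PD", "visit": "followup",
                     "sex": s["sex"], "age": s["age"], "subject_index": idx})
    return pd.DataFrame(rows)


def _fnc_group_stats(fnc_df: pd.DataFrame, integrity: pd.DataFrame,
                     ant_col: str) -> dict:
    """Baseline group comparison, paired longitudinal contrast, and the
    integrity–FNC partial correlation in patients (age/sex adjusted)."""
    base = fnc_df[fnc_df["visit"] == "baseline"]
    cov = np.column_stack([base["age"].to_numpy(),
                           (base["sex"] == "M").astype(float).to_numpy()])
    res_group = adjusted_two_sample_test(base["fisher_z"].to_numpy(),
                                         base["group"].to_numpy(), cov)

    pd_base = base[base["group"] == "PD"]
    fup = fnc_df[fnc_df["visit"] == "followup"].set_index("id")
    paired_ids = [i for i in pd_base["id"] if i in fup.index]
    b = pd_base.set_index("id").loc[paired_ids, "fisher_z"].to_numpy()
    f = fup.loc[paired_ids, "fisher_z"].to_numpy()
    res_paired = paired_test(b, f)

    pdi = pd_base.set_index("id")
    integ = integrity.set_index("id").loc[pdi.index]
    r_pc, p_pc = partial_correlation(
        integ[ant_col].to_numpy(), pdi["fisher_z"].to_numpy(),
        np.column_stack([integ["age"].to_numpy(),
                         (integ["sex"] == "M").astype(float).to_numpy()]),
    )
    return {
        "fnc_mean": {f"{g}:{v}": float(d["r"].mean())
                     for (g, v), d in fnc_df.groupby(["group", "visit"])},
        "group_test": {"effect": res_group.effect, "t": res_group.t,
                       "df": res_group.df, "p": res_group.p},
        "paired_test": {"effect": res_paired.effect, "t": res_paired.t,
                        "df": res_paired.df, "p": res_paired.p},
        "partial_correlation_pd": {"r": r_pc, "p": p_pc},
    }


def table_statistics() -> pd.DataFrame:
    """Summary-statistic tests over the published-style demographic tables."""
    rows = []
    for var in CLINICAL_SPEC_PD:
        if var not in CLINICAL_SPEC_PD_SUBGROUP:
            continue
        m1, s1 = CLINICAL_SPEC_PD[var]
        m2, s2 = CLINICAL_SPEC_PD_SUBGROUP[var]
        t, df, p = summary_ttest(m1, s1, 100, m2, s2, 51)
        rows.append({"table": "whole_vs_subgroup", "variable": var,
                     "stat": t, "df1": df, "df2": np.nan, "p": p})
    for var in ("age", "education", "mmse"):
        groups = [(*CLINICAL_SPEC_PD_SUBGROUP[var], 51),
                  (*CLINICAL_SPEC_PD_FOLLOWUP[var], 51),
                  (*CLINICAL_SPEC_HC[var], 70)]
        F, df1, df2, p = summary_anova(groups)
        rows.append({"table": "longitudinal_threeway", "variable": var,
                     "stat": F, "df1": df1, "df2": df2, "p": p})
    return pd.DataFrame(rows)
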