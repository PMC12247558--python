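"""End-to-end orchestration of the behavioural and imaging arms.

``run_behavioural`` fits the logistic mixed model per data collection and
memory measure, sweeps the confidence cutoff, meta-integrates the
coefficients, regresses pooled effects on the cutoff, and exports
per-subject curiosity slopes (CMLE) for the imaging arm.
``run_imaging`` selects the hemodynamic lag, concatenates the series,
computes pairwise ISC, fits the group LME-CRE and the three IS-RSA models
(unique curiosity, unique memory, Anna-Karenina CMLE), and thresholds the
resulting maps at the whole-brain and ROI level.

Every written file gets a JSON sidecar recording the configuration hash,
seed and package version; the expensive ISC stage is checksum-gated so a
rerun with intact intermediates reloads instead of recomputing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, behaviour, cre, maps, meta, prep, similarity

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_behavioural", "run_imaging"]

MEASURES = {"recognition": 0, "high_confidence": 3, "recall": None}
EFFECTS = ("curiosity_centred", "incentive_code", "curiosity_x_incentive")
ISRSA_MODELS = ("curiosity_unique", "memory_unique", "annak_cmle")


@dataclass
class RunConfig:
    """Single configuration for a full run; flags override YAML values."""

    out_dir: str = "results"
    cutoffs: tuple = (0, 1, 2, 3, 4, 5)
    model_variant: str = "full"
    candidate_lags: tuple = (0, 1, 2, 3, 4, 5, 6)
    fixed_lag: int | None = None
    censor_policy: str = "include"
    p_voxel: float = 0.001
    cluster_k: int = 20
    roi_q: float = 0.05
    roi_k: int = 5
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.p_voxel < 1 or not 0 < self.roi_q < 1:
            raise ValueError("thresholds must lie in (0, 1)")
        if not set(self.cutoffs) <= set(range(6)):
            raise ValueError("cutoffs must be a subset of 0..5")

    @classmethod
    def from_yaml(cls, path, **overrides):
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        for key, value in known.items():
            if key.endswith(("dir",)) and value and not Path(str(value)).parent.exists():
                raise FileNotFoundError(f"configured path does not exist: {value}")
        return cfg

    def hash(self) -> str:
        payload = {k: v for k, v in self.__dict__.items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _sidecar(path: Path, cfg_hash: str, seed: int, **extra) -> None:
    meta_ = {"config_hash": cfg_hash, "seed": seed, "version": __version__, **extra}
    Path(str(path) + ".json").write_text(json.dumps(meta_, indent=2, sort_keys=True) + "\n")


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str, seed: int, **extra) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    _sidecar(path, cfg_hash, seed, **extra)


def _fit_study(table: pd.DataFrame, cutoff: int | None, variant: str, study_id: str):
    """One gLME fit: cutoff=None means cued recall."""
    measure = "recall" if cutoff is None else "recognition"
    outcome = behaviour.code_memory(table, cutoff or 0, measure)
    fit = behaviour.fit_glme(table, outcome.to_numpy(), variant=variant)
    if not fit.converged and variant == "full":
        logger.warning("study %s cutoff %s: full fit unconverged, refitting reduced", study_id, cutoff)
        fit = behaviour.fit_glme(table, outcome.to_numpy(), variant="reduced")
    return fit


def run_behavioural(
    study_tables: dict,
    out_dir,
    cfg: RunConfig | None = None,
    cmle_study: str | None = None,
) -> dict:
    """Behavioural arm over one or more data collections.

    Returns a report dict with per-study estimates, the meta-integrated
    table for the three main memory measures, the cutoff sweep with its
    per-effect regression, and mean-centred CMLE scores from
    ``cmle_study`` (default: the last study, i.e. the imaging sample).
    """
    cfg = cfg or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = cfg.hash()
    if cmle_study is None:
        cmle_study = list(study_tables)[-1]

    tables = {sid: behaviour.centre_curiosity(t) for sid, t in study_tables.items()}
    rows = []
    fits: dict = {}
    jobs = [("recall", None)] + [(f"cutoff{c}", c) for c in cfg.cutoffs]
    for sid, table in tables.items():
        for label, cutoff in jobs:
            fit = _fit_study(table, cutoff, cfg.model_variant, sid)
            fits[sid, label] = fit
            for eff in EFFECTS:
                rows.append(
                    {
                        "study_id": sid,
                        "measure": label,
                        "cutoff": cutoff,
                        "effect": eff,
                        "b": fit.fixed_effects.loc[eff, "b"],
                        "se": fit.fixed_effects.loc[eff, "se"],
                        "z": fit.fixed_effects.loc[eff, "z"],
                        "p": fit.fixed_effects.loc[eff, "p"],
                        "variant": fit.model_variant,
                        "singular": fit.singular,
                        "converged": fit.converged,
                    }
                )
            logger.info("fitted %s / %s", sid, label)
    estimates = pd.DataFrame(rows)
    _write_tsv(estimates, out / "study_estimates.tsv", h, cfg.seed)

    def _pool(measure_label, cutoff):
        pooled = []
        for eff in EFFECTS:
            sub = estimates[(estimates["measure"] == measure_label) & (estimates["effect"] == eff)]
            ests = [
                meta.EffectEstimate(r.study_id, eff, r.b, r.se, cutoff) for r in sub.itertuples()
            ]
            pooled.append(meta.fixed_effect_meta(ests))
        return pooled

    main_results = []
    for name, cutoff in MEASURES.items():
        label = "recall" if cutoff is None else f"cutoff{cutoff}"
        if cutoff is not None and cutoff not in cfg.cutoffs:
            continue
        for m in _pool(label, cutoff):
            main_results.append((name, m))
    table2 = meta.meta_table([m for _, m in main_results])
    table2.insert(0, "measure", [name for name, _ in main_results])
    _write_tsv(table2, out / "meta_table.tsv", h, cfg.seed)

    sweep = {eff: [] for eff in EFFECTS}
    for c in sorted(cfg.cutoffs):
        for m in _pool(f"cutoff{c}", c):
            sweep[m.effect_name].append(m)
    sweep_rows, regressions = [], {}
    for eff, pooled in sweep.items():
        for m in pooled:
            sweep_rows.append(
                {"effect": eff, "cutoff": m.cutoff, "b": m.b_pooled, "se": m.se_pooled,
                 "or": m.odds_ratio, "ci_low": m.ci95_low, "ci_high": m.ci95_high}
            )
        if len(pooled) >= 3:
            slope, ci, p = meta.cutoff_regression(pooled)
            regressions[eff] = {"slope": slope, "ci95": list(ci), "p": p}
    _write_tsv(pd.DataFrame(sweep_rows), out / "cutoff_sweep.tsv", h, cfg.seed)
    (out / "cutoff_regression.json").write_text(json.dumps(regressions, indent=2, sort_keys=True) + "\n")
    _sidecar(out / "cutoff_regression.json", h, cfg.seed)

    cmle_fit = fits[cmle_study, "cutoff3"] if (cmle_study, "cutoff3") in fits else None
    cmle_scores = None
    if cmle_fit is not None and cmle_fit.model_variant == "full":
        cmle_scores = behaviour.extract_cmle(cmle_fit)
        _write_tsv(
            cmle_scores.rename("cmle").reset_index().rename(columns={"index": "subject_id"}),
            out / "cmle_scores.tsv", h, cfg.seed, study=cmle_study,
        )
    return {
        "estimates": estimates,
        "meta_table": table2,
        "cutoff_sweep": pd.DataFrame(sweep_rows),
        "cutoff_regression": regressions,
        "cmle_scores": cmle_scores,
        "fits": fits,
    }


def _trial_vectors(table: pd.DataFrame, column) -> pd.DataFrame:
    """Subjects x stimuli frame in canonical (sorted) stimulus order."""
    values = table.assign(_v=column if not isinstance(column, str) else table[column])
    pivot = values.pivot(index="subject_id", columns="stimulus_id", values="_v")
    return pivot[sorted(pivot.columns)]


def run_imaging(
    series_list,
    trial_table: pd.DataFrame,
    roi_masks: dict | None = None,
    gm_masks: list | None = None,
    cmle_scores: pd.Series | None = None,
    out_dir=None,
    cfg: RunConfig | None = None,
) -> dict:
    """Imaging arm: lag, concatenation, pairwise ISC, LME-CRE, thresholds.

    ``series_list`` are labelled per-subject time series (same subject ids
    as ``trial_table``); ``cmle_scores`` defaults to fitting the
    high-confidence gLME on ``trial_table``.
    """
    cfg = cfg or RunConfig()
    h = cfg.hash()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    grid = series_list[0].data.shape[:3]
    mask = prep.group_gm_mask(gm_masks) if gm_masks else np.ones(grid, dtype=bool)

    labels = {s.subject_id: s.labels for s in series_list}
    if cfg.fixed_lag is not None:
        lag, lag_table = int(cfg.fixed_lag), None
    else:
        lag, lag_table = prep.select_lag(series_list, mask, cfg.candidate_lags)
    plan = prep.build_plan(labels, lag_tr=lag)
    logger.info("lag %d TRs; concatenated length %d volumes", lag, plan.n_volumes)

    subject_ids = [s.subject_id for s in series_list]
    isc_path = out / "isc_values.npz" if out is not None else None
    mapset = None
    if isc_path is not None and isc_path.exists() and Path(str(isc_path) + ".json").exists():
        side = json.loads(Path(str(isc_path) + ".json").read_text())
        if side.get("config_hash") == h:
            cached = np.load(isc_path, allow_pickle=True)
            mapset = similarity.PairwiseMapSet(
                pairs=similarity.subject_pairs(subject_ids),
                values=cached["values"], mask=mask, n_timepoints=int(cached["T"]),
            )
            logger.info("reusing cached pairwise ISC (%s)", isc_path)
    if mapset is None:
        concatenated = {s.subject_id: prep.apply_plan(s, plan) for s in series_list}
        censor = {s.subject_id: s.labels["censor"].to_numpy()[plan.retained_index[s.subject_id]]
                  for s in series_list}
        mapset = similarity.pairwise_isc(concatenated, mask, censor, cfg.censor_policy)
        if isc_path is not None:
            np.savez_compressed(isc_path, values=mapset.values, T=mapset.n_timepoints)
            _sidecar(isc_path, h, cfg.seed, n_pairs=mapset.n_pairs)
    logger.info("%d pairwise ISC maps over %d voxels", mapset.n_pairs, int(mask.sum()))

    groups = pd.Series({s.subject_id: s.group for s in series_list}).loc[subject_ids]
    gcode = similarity.group_code(groups)

    table = behaviour.centre_curiosity(trial_table)
    table = table[table["subject_id"].isin(subject_ids)]
    cur_vec = _trial_vectors(table, "curiosity_centred")
    mem_vec = _trial_vectors(table, behaviour.code_memory(table, 3, "recognition"))
    sim_cur = similarity.trial_similarity(cur_vec.loc[subject_ids], "curiosity")
    sim_mem = similarity.trial_similarity(mem_vec.loc[subject_ids], "memory")
    sims = {
        "curiosity_unique": similarity.residualize(sim_cur, sim_mem),
        "memory_unique": similarity.residualize(sim_mem, sim_cur),
    }
    if cmle_scores is None:
        fit = behaviour.fit_glme(table, behaviour.code_memory(table, 3).to_numpy(), "full")
        cmle_scores = behaviour.extract_cmle(fit)
    sims["annak_cmle"] = similarity.annak_similarity(cmle_scores.loc[subject_ids])

    report = {"lag": lag, "lag_table": lag_table, "mapset": mapset, "plan": plan,
              "models": {}, "roi_tables": {}, "cluster_tables": {}}

    designs = {"group": cre.build_pair_design(subject_ids, group=gcode)}
    for name, sim in sims.items():
        designs[name] = cre.build_pair_design(
            subject_ids, similarity=similarity.grand_mean_centre(sim),
            group=gcode, interaction=True,
        )
    for model_name, fixed in designs.items():
        stat_maps, conv = cre.fit_cre_map(mapset, fixed)
        report["models"][model_name] = {"maps": stat_maps, "converged": conv}
        for eff, smap in stat_maps.items():
            ctab, _ = maps.cluster_threshold(smap, cfg.p_voxel, cfg.cluster_k)
            report["cluster_tables"][model_name, eff] = ctab
            if out is not None:
                _write_tsv(ctab, out / f"clusters_{model_name}_{eff}.tsv", h, cfg.seed,
                           model=model_name, effect=eff)
            for roi_name, roi in (roi_masks or {}).items():
                rtab, _ = maps.roi_fdr(smap, roi, cfg.roi_q, cfg.roi_k)
                report["roi_tables"][model_name, eff, roi_name] = rtab
                if out is not None:
                    _write_tsv(rtab, out / f"roi_{roi_name}_{model_name}_{eff}.tsv", h,
                               cfg.seed, model=model_name, effect=eff, roi=roi_name)
        logger.info("model %s fitted and thresholded", model_name)
    if out is not None and lag_table is not None:
        _write_tsv(lag_table, out / "lag_table.tsv", h, cfg.seed)
    return report
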