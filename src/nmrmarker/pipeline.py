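"""End-to-end orchestration: simulate -> preprocess -> model -> select ->
power -> pathways, with deterministic seeding and restartable artifacts.

A single global seed drives everything: the study simulation uses it
directly, and each (sample type, comparison) model derives its own seed by
a fixed splitting rule, so partial re-runs reproduce the full run's
numbers exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemometrics as chem
from . import markers as mk
from . import pathway as pw
from . import power as pwr
from . import preprocess as pre
from . import synthdata as syn

log = logging.getLogger("nmrmarker")

COMPARISONS = ("SMFY", "GMFS")


@dataclass
class RunConfig:
    """Flat run configuration; unknown keys in a YAML file are rejected."""

    seed: int = 1
    groups: tuple = syn.GROUPS
    n_per_group: int = 8
    sample_types: tuple = syn.SAMPLE_TYPES
    bucket_width: float = pre.DEFAULT_BUCKET_WIDTH
    pqn_reference_group: str = "control"
    reference_mode: str = "none"  # none | auto (lactate for serum, TSP otherwise)
    folds: int = 7
    n_permutations: int = 200
    max_orth: int = 5
    r_min: float = 0.6
    vip_top_fraction: float = 0.20
    p_max: float = 0.05
    min_abs_log2fc: float = 0.1
    power_alpha: float = 0.01
    noise_sd: float = syn.DEFAULT_NOISE_SD
    min_abs_log2_effect: float | None = None
    out_dir: str = "results"

    def __post_init__(self):
        if self.bucket_width <= 0:
            raise ValueError("bucket_width must be positive")
        if self.pqn_reference_group not in self.groups:
            raise ValueError("pqn_reference_group not among groups")
        # criteria validity is enforced by SelectionCriteria
        self.criteria()

    def criteria(self) -> mk.SelectionCriteria:
        return mk.SelectionCriteria(
            r_min=self.r_min,
            vip_top_fraction=self.vip_top_fraction,
            p_max=self.p_max,
            min_abs_log2fc=self.min_abs_log2fc,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("groups", "sample_types"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = list(self.groups)
        d["sample_types"] = list(self.sample_types)
        return d


@dataclass
class RunReport:
    config: RunConfig
    seed: int
    per_sample_type: dict  # sample_type -> dict of stage outputs
    enrichment: dict  # comparison -> DataFrame
    artifacts: list = field(default_factory=list)


def stage_seed(base_seed: int, sample_type: str, comparison: str = "") -> int:
    """Deterministic per-stage seed below 2**31."""
    order = list(syn.SAMPLE_TYPES) + ["*"]
    st = order.index(sample_type) if sample_type in order else len(order)
    cmp_i = {"": 0, "SMFY": 1, "GMFS": 2}.get(comparison, 3)
    return (base_seed * 101 + st * 11 + cmp_i) % (2**31 - 1)


def preprocess_sample_type(spectra, config: RunConfig, groups):
    """Exclusions -> bucketing -> total-area -> PQN for one sample type."""
    plan = pre.default_exclusion_plan()
    if config.reference_mode == "auto":
        mode = {"serum": "lactate"}.get(spectra[0].sample_type, "tsp")
        spectra = [pre.reference_shift(sp, mode) for sp in spectra]
    gapped = [pre.apply_exclusions(sp, plan) for sp in spectra]
    bm = pre.bucket_spectra(gapped, width=config.bucket_width)
    bm = pre.total_area_normalize(bm)
    bm = pre.pqn_normalize(bm, groups=groups, reference_group=config.pqn_reference_group)
    return bm


def _comparison_analysis(bm, meta_groups, comparison, config, library, seed):
    """Pareto scaling, OPLS-DA (+ optional permutation test), volcano
    selection and power for one treated-vs-control comparison."""
    groups = np.asarray(meta_groups)
    pair = np.isin(groups, [comparison, config.pqn_reference_group])
    X_raw = bm.values[pair]
    y = np.where(groups[pair] == comparison, 1.0, -1.0)
    folds = min(config.folds, len(y))  # degenerate tiny designs still run
    scaler = chem.SpectralScaler(mode="pareto").fit(X_raw)
    X = scaler.transform(X_raw)
    model = chem.OPLSDA(
        n_orth="auto", max_orth=config.max_orth, cv_folds=folds,
        random_state=seed,
    ).fit(X, y)
    validation = None
    if config.n_permutations > 0:
        validation = chem.permutation_test(
            X, y, n_perm=config.n_permutations, seed=seed,
            model=chem.OPLSDA(n_orth=model.n_orth_, random_state=seed,
                              cv_folds=folds),
            folds=folds,
        )
    regions = mk.default_quant_regions(library, bm.sample_type)
    quant_all = mk.quantify_metabolites(bm, regions)
    quant = quant_all.loc[np.asarray(bm.sample_ids)[pair]]
    edges_kept = bm.edges[scaler.kept_columns_]
    records = mk.build_volcano_table(
        quant, model, edges_kept, bm.width, regions, groups[pair], comparison,
        criteria=config.criteria(), control_group=config.pqn_reference_group,
        sample_type=bm.sample_type,
    )
    power_table = pwr.power_report(
        records, quant, groups[pair], alpha=config.power_alpha,
        control_group=config.pqn_reference_group,
    )
    return {
        "scaler": scaler,
        "model": model,
        "validation": validation,
        "regions": regions,
        "quant": quant_all,
        "markers": records,
        "power": power_table,
        "diagnostics": {
            "r2x": model.r2x_,
            "r2y": model.r2y_,
            "q2": model.q2_,
            "n_orth": model.n_orth_,
            "p_perm": None if validation is None else validation.p_perm,
        },
    }


def run_pipeline(config: RunConfig, out_dir=None) -> RunReport:
    """Execute every stage for each sample type and both treated-vs-control
    comparisons; identical seed implies an identical report."""
    t0 = time.time()
    if config.n_per_group < 3:
        warnings.warn(
            "fewer than 3 samples per group: power estimates are uninterpretable",
            stacklevel=2,
        )
    library = syn.build_default_library()
    effects = syn.default_effects(min_abs_log2=config.min_abs_log2_effect)
    design = syn.StudyDesign(
        groups=tuple(config.groups),
        n_per_group=config.n_per_group,
        sample_types=tuple(config.sample_types),
    )
    study = syn.simulate_study(
        design=design, library=library, effects=effects,
        noise_sd=config.noise_sd, seed=config.seed,
    )
    log.info("simulated study (seed %d) in %.1fs", config.seed, time.time() - t0)

    comparisons = [g for g in COMPARISONS if g in config.groups]
    per_type: dict = {}
    for st in config.sample_types:
        t_st = time.time()
        meta = study.metadata[study.metadata["sample_type"] == st].set_index("sample_id")
        spectra = study.spectra[st]
        groups = meta.loc[[sp.sample_id for sp in spectra], "group"].to_numpy()
        try:
            bm = preprocess_sample_type(spectra, config, groups)
            # overview models on all groups
            ctr = chem.SpectralScaler(mode="center").fit(bm.values)
            pca = chem.NipalsPCA(n_components=2).fit(ctr.transform(bm.values))
            par = chem.SpectralScaler(mode="pareto").fit(bm.values)
            onehot = pd.get_dummies(pd.Series(groups)).to_numpy(dtype=float)
            pls = chem.PLSDA(n_components=2).fit(par.transform(bm.values), onehot)
            result = {
                "buckets": bm,
                "bucket_count": len(bm.edges),
                "pca": pca,
                "pls": pls,
                "groups": groups,
                "comparisons": {},
            }
            for comparison in comparisons:
                seed = stage_seed(config.seed, st, comparison)
                result["comparisons"][comparison] = _comparison_analysis(
                    bm, groups, comparison, config, library, seed
                )
        except Exception as exc:
            raise RuntimeError(f"pipeline stage failed for {st!r}: {exc}") from exc
        per_type[st] = result
        log.info("sample type %s done in %.1fs", st, time.time() - t_st)

    # pathway enrichment on the union of selected markers per comparison
    demo = pw.build_demo_pathways()
    enrichment = {}
    for comparison in comparisons:
        selected = set()
        for st in config.sample_types:
            rec = per_type[st]["comparisons"][comparison]["markers"]
            selected |= set(rec.loc[rec["selected"], "metabolite"])
        enrichment[comparison] = pw.enrich_pathways(selected, demo)

    report = RunReport(
        config=config, seed=config.seed, per_sample_type=per_type,
        enrichment=enrichment,
    )
    if out_dir is not None:
        report.artifacts = write_report(report, study, Path(out_dir))
    log.info("pipeline done in %.1fs", time.time() - t0)
    return report


# ---------------------------------------------------------------------------
# Artifact writing
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_report(report: RunReport, study, out_dir: Path) -> list:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list = []

    def _note(p: Path):
        written.append(p)
        return p

    syn.write_metadata_tsv(study.metadata, _note(out_dir / "metadata.tsv"))
    syn.write_ground_truth_tsv(study.ground_truth, _note(out_dir / "ground_truth.tsv"))
    with open(_note(out_dir / "config.json"), "w") as fh:
        json.dump(report.config.to_dict(), fh, indent=1)

    for st, res in report.per_sample_type.items():
        d = out_dir / st
        d.mkdir(exist_ok=True)
        bm = res["buckets"]
        plan = pre.default_exclusion_plan()
        bm.write_tsv(
            _note(d / "buckets.tsv"), _note(d / "buckets.json"),
            extra={
                "retained_ppm": list(plan.retained[st]),
                "excluded_ppm": [list(iv) for iv in plan.excluded[st]],
            },
        )
        scores = pd.DataFrame(
            {
                "sample_id": bm.sample_ids,
                "group": res["groups"],
                "pc1": res["pca"].scores_[:, 0],
                "pc2": res["pca"].scores_[:, 1] if res["pca"].n_components_ > 1 else np.nan,
                "pls_t1": res["pls"].x_scores_[:, 0],
                "pls_t2": res["pls"].x_scores_[:, 1] if res["pls"].n_components_ > 1 else np.nan,
            }
        )
        scores.to_csv(_note(d / "scores.tsv"), sep="\t", index=False, float_format="%.6g")
        for comparison, cres in res["comparisons"].items():
            prefix = d / comparison
            mk.write_marker_tsv(cres["markers"], _note(prefix.with_suffix(".markers.tsv")))
            mk.volcano_plot_data(cres["markers"]).to_csv(
                _note(prefix.with_suffix(".volcano.tsv")), sep="\t", index=False,
                float_format="%.6g",
            )
            cres["power"].to_csv(
                _note(prefix.with_suffix(".power.tsv")), sep="\t", index=False,
                float_format="%.6g",
            )
            model = cres["model"]
            opls_scores = pd.DataFrame({"t_pred": model.t_pred_})
            for a in range(model.n_orth_):
                opls_scores[f"t_orth{a + 1}"] = model.T_orth_[:, a]
            opls_scores.to_csv(
                _note(prefix.with_suffix(".opls_scores.tsv")), sep="\t", index=False,
                float_format="%.6g",
            )
            export = {
                "sample_type": st,
                "comparison": comparison,
                "diagnostics": cres["diagnostics"],
                "seed": int(model.random_state),
                "w_pred": model.w_pred_.tolist(),
                "p_pred": model.p_pred_.tolist(),
                "vip": model.vip_.tolist(),
                "r_loadings": model.r_loadings_.tolist(),
            }
            if cres["validation"] is not None:
                export["permutation_q2"] = cres["validation"].permutation_q2.tolist()
                export["permutation_r2y"] = cres["validation"].permutation_r2y.tolist()
            with open(_note(prefix.with_suffix(".model.json")), "w") as fh:
                json.dump(export, fh)
    for comparison, table in report.enrichment.items():
        table.to_csv(
            _note(out_dir / f"enrichment_{comparison}.tsv"), sep="\t", index=False,
            float_format="%.6g",
        )
    manifest = {
        "seed": report.seed,
        "artifacts": [
            {"path": str(p.relative_to(out_dir)), "sha256": _sha256(p)} for p in written
        ],
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return written + [out_dir / "manifest.json"]
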