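"""End-to-end orchestration: simulate -> profile -> split -> train -> evaluate -> report.

Every stage persists its outputs as plain-text tables under the output
directory, and later stages read those intermediates, so a partially
completed run can be resumed stage by stage (the CLI exposes each stage
as a subcommand). All randomness derives from a single root seed
through named substreams (simulation, split, model, bootstrap), so any
stage can be reproduced in isolation.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import RFConfig, cross_validate, fit_final, predict_scores
from .cohort import (
    SampleMeta,
    baseline_table,
    read_sample_sheet,
    stratified_split,
    write_sample_sheet,
    write_split,
)
from .errors import ConfigurationError
from .evaluation import (
    anova_scores,
    auc_ci_delong,
    confusion_metrics,
    heatmap_order,
    motif_group_tests,
    roc_curve,
    roc_table,
    subgroup_roc,
    youden_threshold,
)
from .motifs import enumerate_motifs
from .profiling import (
    QCParams,
    build_matrix,
    counts_to_frequencies,
    profile_sample,
    read_matrix,
    write_counts,
    write_matrix,
)
from .simulation import (
    LengthMixture,
    SimulationConfig,
    _MotifPositionLookup,
    class_motif_spectrum,
    make_reference,
    sample_profile,
    simulate_cohort_profiles,
    simulate_fragments,
    write_alignments,
    write_reference_fasta,
)

logger = logging.getLogger(__name__)

_SUBSTREAMS = ("simulation", "split", "folds", "forest", "bootstrap")


def derive_seeds(root_seed: int) -> dict[str, int]:
    """Named per-stage seeds spawned from one root seed (all < 2^31)."""
    children = np.random.SeedSequence(root_seed).spawn(len(_SUBSTREAMS))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_SUBSTREAMS, children)
    }


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from a YAML file."""

    output_dir: Path
    task: str = "cancer"  # "cancer" or "immunotherapy"
    seed: int = 0
    split_ratio: float = 0.7
    threshold_policy: str = "youden-train"  # or "youden-self"
    reference_path: Path | None = None
    alignments_dir: Path | None = None
    matrix_path: Path | None = None
    sample_sheet_path: Path | None = None
    simulate: SimulationConfig | None = None
    simulate_mode: str = "profiles"  # "profiles" or "fragments"
    simulate_reference_length: int = 100_000
    simulate_reference_gc: float = 0.5
    qc: QCParams = field(default_factory=QCParams)
    rf: RFConfig = field(default_factory=RFConfig)

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if self.task not in ("cancer", "immunotherapy"):
            raise ConfigurationError(f"task must be cancer|immunotherapy, got {self.task!r}")
        if self.threshold_policy not in ("youden-train", "youden-self"):
            raise ConfigurationError(
                f"threshold_policy must be youden-train|youden-self, got {self.threshold_policy!r}"
            )
        if self.simulate_mode not in ("profiles", "fragments"):
            raise ConfigurationError("simulate_mode must be 'profiles' or 'fragments'")
        for attr in ("reference_path", "alignments_dir", "matrix_path", "sample_sheet_path"):
            value = getattr(self, attr)
            if value is not None:
                value = Path(value)
                setattr(self, attr, value)
                if not value.exists():
                    raise ConfigurationError(f"{attr} does not exist: {value}")
        if self.simulate is None and self.matrix_path is None and self.alignments_dir is None:
            raise ConfigurationError(
                "nothing to run: provide simulate settings, a matrix_path or alignments_dir"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "qc" in raw and isinstance(raw["qc"], dict):
            raw["qc"] = QCParams(**raw["qc"])
        if "rf" in raw and isinstance(raw["rf"], dict):
            raw["rf"] = RFConfig(**raw["rf"])
        if "simulate" in raw and isinstance(raw["simulate"], dict):
            sim = dict(raw["simulate"])
            if "length_dist" in sim and isinstance(sim["length_dist"], dict):
                sim["length_dist"] = LengthMixture(**sim["length_dist"])
            raw["simulate"] = SimulationConfig(**sim)
        return cls(**raw)

    def config_hash(self) -> str:
        def _default(obj: Any):
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if hasattr(obj, "__dict__"):
                return vars(obj)
            return str(obj)

        payload = {k: v for k, v in vars(self).items()}
        for key in ("qc", "rf", "simulate"):
            if payload.get(key) is not None:
                payload[key] = asdict(payload[key])
        blob = json.dumps(payload, sort_keys=True, default=_default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def simulate_stage(config: PipelineConfig) -> tuple[pd.DataFrame, list[SampleMeta]]:
    """Generate the synthetic cohort and persist matrix + sample sheet.

    ``profiles`` mode draws per-sample motif frequencies directly
    (Dirichlet-multinomial); ``fragments`` mode additionally writes a
    reference FASTA and one coordinate-sorted SAM per sample, then the
    profile stage recovers the matrix from those files.
    """
    assert config.simulate is not None
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed)
    sim = replace(config.simulate, seed=seeds["simulation"])
    reference = make_reference(
        config.simulate_reference_length,
        config.simulate_reference_gc,
        seed=seeds["simulation"],
    )
    if sim.base_freqs is None:
        sim = sim.with_reference_base_freqs(reference)
    if config.simulate_mode == "profiles":
        matrix, metas = simulate_cohort_profiles(sim)
    else:
        ref_path = out / "reference.fa"
        write_reference_fasta(reference, ref_path)
        config.reference_path = ref_path
        lookup = _MotifPositionLookup(reference)
        aln_dir = out / "alignments"
        aln_dir.mkdir(exist_ok=True)
        rng = np.random.default_rng(seeds["simulation"])
        metas = simulate_cohort_profiles(sim)[1]
        truth_rows = {}
        for meta in metas:
            spectrum = class_motif_spectrum(sim, meta.label)
            alpha = np.maximum(sim.dirichlet_concentration * spectrum, 1e-9)
            sample_spectrum = rng.dirichlet(alpha)
            frag_seed = int(rng.integers(0, 2**31))
            fragments, truth = simulate_fragments(
                sample_spectrum,
                reference,
                sim.fragments_per_sample,
                sim.length_mixture_for(meta.label),
                seed=frag_seed,
                lookup=lookup,
            )
            write_alignments(fragments, reference, aln_dir / f"{meta.sample_id}.sam")
            truth_rows[meta.sample_id] = truth
        pd.DataFrame.from_dict(
            truth_rows, orient="index", columns=list(enumerate_motifs())
        ).rename_axis("sample_id").to_csv(out / "ground_truth_counts.tsv", sep="\t")
        config.alignments_dir = aln_dir
        matrix = profile_stage(config, metas)
    write_matrix(matrix, out / "matrix.tsv")
    write_sample_sheet(metas, out / "sample_sheet.tsv")
    return matrix, metas


def profile_stage(config: PipelineConfig, metas: Sequence[SampleMeta]) -> pd.DataFrame:
    """Profile every sample's alignment file into the cohort matrix."""
    assert config.alignments_dir is not None and config.reference_path is not None
    out = config.output_dir / "profiles"
    out.mkdir(parents=True, exist_ok=True)
    profiles = []
    for meta in metas:
        sam = Path(config.alignments_dir) / f"{meta.sample_id}.sam"
        counts = profile_sample(sam, config.reference_path, config.qc, meta.sample_id)
        write_counts(counts, out / f"{meta.sample_id}.counts.tsv")
        profiles.append(counts_to_frequencies(counts))
    return build_matrix(profiles)


def _load_inputs(config: PipelineConfig) -> tuple[pd.DataFrame, list[SampleMeta]]:
    if config.simulate is not None:
        return simulate_stage(config)
    metas = read_sample_sheet(config.sample_sheet_path)
    if config.matrix_path is not None:
        matrix = read_matrix(config.matrix_path)
    else:
        matrix = profile_stage(config, metas)
        write_matrix(matrix, config.output_dir / "matrix.tsv")
    return matrix, metas


def _roc_summary(name: str, scores, labels, positive_label, threshold) -> dict:
    roc = roc_curve(scores, labels, positive_label)
    if roc.n_pos >= 2 and roc.n_neg >= 2:
        lo, hi = auc_ci_delong(scores, labels, positive_label=positive_label)
    else:
        lo = hi = float("nan")
    cm = confusion_metrics(scores, labels, threshold, positive_label)
    return {
        "cohort": name,
        "n_pos": roc.n_pos,
        "n_neg": roc.n_neg,
        "auc": roc.auc,
        "auc_ci_low": lo,
        "auc_ci_high": hi,
        **cm.as_dict(),
    }


def _age_band(age: float | None) -> str | None:
    if age is None:
        return None
    return "<60" if age < 60 else ("60-70" if age < 70 else ">70")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns a dict of headline results (also persisted as summary.json);
    any stage failure aborts with the stage name while earlier outputs
    remain on disk.
    """
    t0 = time.time()
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed)
    stage = "inputs"
    try:
        matrix, metas = _load_inputs(config)
        by_id = {m.sample_id: m for m in metas}
        labels_all = pd.Series({m.sample_id: m.label for m in metas}).loc[matrix.index]
        if config.task == "immunotherapy":
            return _run_immunotherapy(config, matrix, metas, seeds, t0)

        stage = "split"
        split = stratified_split(metas, config.split_ratio, seeds["split"])
        write_split(split, out / "split.tsv")
        baseline = baseline_table(metas, split)
        baseline.to_csv(out / "baseline_table.tsv", sep="\t", index=False)
        train_ids = [s for s in matrix.index if s in set(split.train_ids)]
        test_ids = [s for s in matrix.index if s in set(split.test_ids)]
        train_m, test_m = matrix.loc[train_ids], matrix.loc[test_ids]
        train_y, test_y = labels_all.loc[train_ids], labels_all.loc[test_ids]

        stage = "train"
        rf = replace(config.rf, seed=seeds["forest"])
        oof_scores = cross_validate(train_m, train_y, rf)
        oof_scores.rename("score").to_csv(out / "train_oof_scores.tsv", sep="\t")
        model = fit_final(train_m, train_y, rf)
        model.save(out / "model.joblib")
        model.ranking.as_frame().to_csv(out / "importance_ranking.tsv", sep="\t", index=False)
        pd.Series(model.selected_motifs, name="motif").to_csv(
            out / "selected_motifs.tsv", sep="\t", index=False
        )

        stage = "evaluate"
        train_roc = roc_curve(oof_scores, train_y, "cancer")
        train_threshold = youden_threshold(train_roc)
        test_scores = predict_scores(model, test_m)
        test_scores.to_csv(out / "test_scores.tsv", sep="\t")
        if config.threshold_policy == "youden-self":
            test_threshold = youden_threshold(roc_curve(test_scores, test_y, "cancer"))
        else:
            test_threshold = train_threshold
        summary_rows = [
            _roc_summary("train_oof", oof_scores, train_y, "cancer", train_threshold),
            _roc_summary("test", test_scores, test_y, "cancer", test_threshold),
        ]
        roc_table(train_roc).to_csv(out / "roc_train_oof.tsv", sep="\t", index=False)
        roc_table(roc_curve(test_scores, test_y, "cancer")).to_csv(
            out / "roc_test.tsv", sep="\t", index=False
        )
        # subgroup ROC on the combined cohort, scored by the final model
        all_scores = predict_scores(model, matrix)
        all_scores.to_csv(out / "all_scores.tsv", sep="\t")
        subgroup_rows = []
        for group_by in ("cancer_type", "stage"):
            for name, roc in subgroup_roc(all_scores, metas, group_by).items():
                thr = youden_threshold(roc)
                sub_ids = [
                    s
                    for s in matrix.index
                    if by_id[s].label == "healthy"
                    or (
                        group_by == "cancer_type"
                        and by_id[s].cancer_type == name
                    )
                    or (
                        group_by == "stage"
                        and by_id[s].stage is not None
                        and by_id[s].stage in DEFAULT_STAGE_LOOKUP.get(name, (name,))
                    )
                ]
                row = _roc_summary(
                    f"{group_by}:{name}",
                    all_scores.loc[sub_ids],
                    labels_all.loc[sub_ids],
                    "cancer",
                    thr,
                )
                subgroup_rows.append(row)
        summary_rows.extend(subgroup_rows)
        summary = pd.DataFrame(summary_rows)
        summary.to_csv(out / "summary.tsv", sep="\t", index=False, float_format="%.6g")

        tests = motif_group_tests(matrix, labels_all, "cancer", model.selected_motifs)
        tests.to_csv(out / "motif_tests.tsv", sep="\t", index=False, float_format="%.6g")
        all_tests = motif_group_tests(matrix, labels_all, "cancer")
        all_tests.to_csv(out / "motif_tests_all.tsv", sep="\t", index=False, float_format="%.6g")

        anova_rows = []
        for covariate, getter in (
            ("sex", lambda m: m.sex),
            ("bmi_class", lambda m: m.bmi_class),
            ("age_band", lambda m: _age_band(m.age)),
        ):
            strata = [getter(by_id[s]) for s in matrix.index]
            keep = [i for i, v in enumerate(strata) if v is not None]
            if len({strata[i] for i in keep}) >= 2:
                f, p = anova_scores(
                    all_scores.iloc[keep].to_numpy(), [strata[i] for i in keep]
                )
                anova_rows.append({"covariate": covariate, "F": f, "p_value": p})
        pd.DataFrame(anova_rows).to_csv(
            out / "anova_scores.tsv", sep="\t", index=False, float_format="%.6g"
        )

        sel = list(model.selected_motifs)
        row_order, col_order, scaled = heatmap_order(matrix[sel])
        scaled.to_csv(out / "heatmap_scaled.tsv", sep="\t", float_format="%.6g")
        pd.DataFrame(
            {"axis": ["row"] * len(row_order) + ["col"] * len(col_order),
             "position": list(range(len(row_order))) + list(range(len(col_order))),
             "name": [scaled.index[i] for i in row_order] + [scaled.columns[j] for j in col_order]}
        ).to_csv(out / "heatmap_order.tsv", sep="\t", index=False)

        results = {
            "task": "cancer",
            "n_samples": len(matrix),
            "n_train": len(train_ids),
            "n_test": len(test_ids),
            "train_oof_auc": train_roc.auc,
            "test_auc": float(summary.loc[summary.cohort == "test", "auc"].iloc[0]),
            "selected_motifs": sel,
            "train_threshold": train_threshold,
            "summary_rows": summary_rows,
        }
    except Exception as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "cfmotif_version": __version__,
        "config_hash": config.config_hash(),
        "root_seed": config.seed,
        "substream_seeds": seeds,
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(out / "summary.json", "w") as fh:
        json.dump(results, fh, indent=2, default=float)
    return results


DEFAULT_STAGE_LOOKUP = {"II-III": ("II", "III"), "IV": ("IV",)}


def _run_immunotherapy(config, matrix, metas, seeds, t0) -> dict:
    """Response/non-response model on the immunotherapy subset.

    With the small treated cohort there is no holdout; the model is
    evaluated by out-of-fold CV scores only, and the final refit is kept
    for its importance ranking and motif selection.
    """
    out = config.output_dir
    subset = [m for m in metas if m.immunotherapy and m.response is not None]
    ids = [m.sample_id for m in subset if m.sample_id in matrix.index]
    sub_m = matrix.loc[ids]
    labels = pd.Series({m.sample_id: m.response for m in subset}).loc[ids]
    rf = replace(config.rf, seed=seeds["forest"], top_k=min(config.rf.top_k, 6))
    oof = cross_validate(sub_m, labels, rf, positive_label="response")
    oof.rename("score").to_csv(out / "immunotherapy_oof_scores.tsv", sep="\t")
    model = fit_final(sub_m, labels, rf, positive_label="response")
    model.save(out / "immunotherapy_model.joblib")
    model.ranking.as_frame().to_csv(
        out / "immunotherapy_ranking.tsv", sep="\t", index=False
    )
    roc = roc_curve(oof, labels, "response")
    thr = youden_threshold(roc)
    roc_table(roc).to_csv(out / "roc_immunotherapy_oof.tsv", sep="\t", index=False)
    summary = [_roc_summary("immunotherapy_oof", oof, labels, "response", thr)]
    pd.DataFrame(summary).to_csv(
        out / "summary.tsv", sep="\t", index=False, float_format="%.6g"
    )
    results = {
        "task": "immunotherapy",
        "n_samples": len(ids),
        "n_response": int((labels == "response").sum()),
        "n_non_response": int((labels == "non_response").sum()),
        "oof_auc": roc.auc,
        "selected_motifs": list(model.selected_motifs),
        "summary_rows": summary,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(results, fh, indent=2, default=float)
    manifest = {
        "cfmotif_version": __version__,
        "config_hash": config.config_hash(),
        "root_seed": config.seed,
        "substream_seeds": seeds,
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return results


def make_report(output_dir: str | Path) -> Path:
    """Assemble figures and a markdown report from a completed run's bundle.

    Every number in the report is read back from the persisted TSV/JSON
    outputs, never recomputed, so the report always matches the bundle.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(output_dir)
    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    with open(out / "summary.json") as fh:
        results = json.load(fh)
    summary = pd.read_csv(out / "summary.tsv", sep="\t")

    lines = ["# cfDNA end-motif analysis report", ""]
    lines.append(f"Task: **{results['task']}** — {results['n_samples']} samples.")
    lines.append("")
    lines.append("## Performance summary")
    lines.append("")
    lines.append(summary.to_markdown(index=False))
    lines.append("")

    # ROC curves
    roc_files = sorted(out.glob("roc_*.tsv"))
    if roc_files:
        fig, ax = plt.subplots(figsize=(5, 5))
        for f in roc_files:
            pts = pd.read_csv(f, sep="\t")
            name = f.stem.replace("roc_", "")
            ax.plot(1 - pts["specificity"], pts["sensitivity"], label=name)
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        fig.savefig(fig_dir / "roc.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        lines += ["## ROC curves", "", "![ROC](figures/roc.png)", ""]

    ranking_file = (
        out / "importance_ranking.tsv"
        if (out / "importance_ranking.tsv").exists()
        else out / "immunotherapy_ranking.tsv"
    )
    if ranking_file.exists():
        ranking = pd.read_csv(ranking_file, sep="\t")
        top = ranking.head(len(results["selected_motifs"]))
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.barh(top["motif"][::-1], top["mean_decrease_accuracy"][::-1])
        ax.set_xlabel("mean decrease accuracy")
        fig.savefig(fig_dir / "importance.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        lines += [
            "## Variable importance (selected motifs)",
            "",
            "![importance](figures/importance.png)",
            "",
        ]

    if (out / "matrix.tsv").exists() and (out / "sample_sheet.tsv").exists():
        matrix = read_matrix(out / "matrix.tsv")
        metas = read_sample_sheet(out / "sample_sheet.tsv")
        lab = pd.Series({m.sample_id: m.label for m in metas}).loc[matrix.index]
        sel = results["selected_motifs"]
        fig, axes = plt.subplots(1, len(sel), figsize=(1.1 * len(sel), 3), sharey=False)
        for ax, motif in zip(np.atleast_1d(axes), sel):
            groups = [matrix.loc[lab == g, motif] for g in sorted(lab.unique())]
            ax.boxplot(groups, tick_labels=sorted(lab.unique()))
            ax.set_title(motif, fontsize=8)
            ax.tick_params(axis="x", labelrotation=90, labelsize=6)
            ax.tick_params(axis="y", labelsize=6)
        fig.savefig(fig_dir / "motif_boxplots.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        lines += [
            "## Selected motif frequencies by group",
            "",
            "![boxplots](figures/motif_boxplots.png)",
            "",
        ]
        if (out / "all_scores.tsv").exists():
            scores = pd.read_csv(out / "all_scores.tsv", sep="\t", index_col=0)["score"]
            by_type: dict[str, list[float]] = {}
            for m in metas:
                if m.sample_id not in scores.index:
                    continue
                key = m.cancer_type or ("healthy" if m.label == "healthy" else "cancer")
                by_type.setdefault(key, []).append(float(scores[m.sample_id]))
            fig, ax = plt.subplots(figsize=(5, 3.5))
            keys = sorted(by_type)
            ax.boxplot([by_type[k] for k in keys], tick_labels=keys)
            ax.set_ylabel("cancer score")
            ax.tick_params(axis="x", labelrotation=30)
            fig.savefig(fig_dir / "scores_by_type.png", dpi=120, bbox_inches="tight")
            plt.close(fig)
            lines += [
                "## Cancer-score distributions",
                "",
                "![scores](figures/scores_by_type.png)",
                "",
            ]
        if (out / "heatmap_scaled.tsv").exists():
            scaled = pd.read_csv(out / "heatmap_scaled.tsv", sep="\t", index_col=0)
            order = pd.read_csv(out / "heatmap_order.tsv", sep="\t")
            rows = order.loc[order.axis == "row", "name"]
            cols = order.loc[order.axis == "col", "name"]
            fig, ax = plt.subplots(figsize=(5, 6))
            im = ax.imshow(scaled.loc[rows, cols], aspect="auto", cmap="RdBu_r")
            ax.set_xticks(range(len(cols)), cols, rotation=90, fontsize=6)
            ax.set_yticks([])
            fig.colorbar(im, ax=ax, label="z-scaled frequency")
            fig.savefig(fig_dir / "heatmap.png", dpi=120, bbox_inches="tight")
            plt.close(fig)
            lines += ["## Heatmap (clustered)", "", "![heatmap](figures/heatmap.png)", ""]

    report_path = out / "report.md"
    report_path.write_text("\n".join(lines))
    return report_path
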