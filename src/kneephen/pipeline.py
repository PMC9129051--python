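"""End-to-end orchestration: prepare -> bicluster -> validate -> trajectories
-> outcomes -> report, from one config, with a self-describing manifest.

Every stage writes its artifacts as delimited text / JSON so a rerun with
the same config reproduces them bit-for-bit; stage timings go to a
separate run log so the manifest itself stays stable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import biclustering, outcomes, preprocess, sigclust, synthetic, trajectory

__all__ = ["PipelineConfig", "run_pipeline", "render_reports"]


@dataclass
class PipelineConfig:
    """Validated configuration for one analysis run.

    Exactly one of ``input_paths`` (baseline/metadata/panel/outcomes files)
    or ``synthetic_spec`` must be present.
    """

    output_dir: str
    input_paths: Optional[dict] = None
    synthetic_spec: Optional[synthetic.SyntheticSpec] = None
    delta: float = 0.2
    max_k: int = 6
    min_rows: int = 2
    sigclust_n_sim: int = 1000
    sigclust_restarts: int = 10
    sigclust_seed: int = 0
    gbtm_G_max: int = 4
    gbtm_seed: int = 0
    gbtm_dropout: bool = False
    gbtm_n_starts: int = 10
    figures: bool = True

    def validate(self):
        if not (0.0 < self.delta < 1.0):
            raise ValueError("delta must be in (0, 1)")
        if (self.input_paths is None) == (self.synthetic_spec is None):
            raise ValueError("exactly one of input_paths / synthetic_spec required")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        spec = raw.get("synthetic_spec")
        if spec is not None:
            if spec == "default":
                spec = synthetic.default_spec(
                    seed=raw.get("seed", 0),
                    n_rows=raw.get("n_rows", 1200),
                    n_cols=raw.get("n_cols", 86),
                )
            elif isinstance(spec, dict):
                spec = synthetic.SyntheticSpec.from_dict(spec)
        cfg = cls(
            output_dir=raw["output_dir"],
            input_paths=raw.get("input_paths"),
            synthetic_spec=spec,
            delta=raw.get("delta", 0.2),
            max_k=raw.get("max_k", 6),
            min_rows=raw.get("min_rows", 2),
            sigclust_n_sim=raw.get("sigclust", {}).get("n_sim", 1000),
            sigclust_restarts=raw.get("sigclust", {}).get("restarts", 10),
            sigclust_seed=raw.get("sigclust", {}).get("seed", 0),
            gbtm_G_max=raw.get("gbtm", {}).get("G_max", 4),
            gbtm_seed=raw.get("gbtm", {}).get("seed", 0),
            gbtm_dropout=raw.get("gbtm", {}).get("dropout", False),
            gbtm_n_starts=raw.get("gbtm", {}).get("n_starts", 10),
            figures=raw.get("figures", True),
        )
        cfg.validate()
        return cfg

    def echo(self) -> dict:
        d = {
            "output_dir": self.output_dir,
            "delta": self.delta,
            "max_k": self.max_k,
            "min_rows": self.min_rows,
            "sigclust": {"n_sim": self.sigclust_n_sim,
                         "restarts": self.sigclust_restarts,
                         "seed": self.sigclust_seed},
            "gbtm": {"G_max": self.gbtm_G_max, "seed": self.gbtm_seed,
                     "dropout": self.gbtm_dropout, "n_starts": self.gbtm_n_starts},
            "figures": self.figures,
        }
        if self.input_paths is not None:
            d["input_paths"] = dict(self.input_paths)
        if self.synthetic_spec is not None:
            d["synthetic_spec"] = self.synthetic_spec.to_dict()
        return d


def _sha256(path: Path) -> Optional[str]:
    # only text artifacts are hashed: figures may differ byte-wise between
    # renderer versions while the underlying CSV twins stay identical
    if Path(path).suffix.lower() in (".png", ".svg", ".pdf"):
        return None
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns (and writes) the run manifest.

    Stage failures surface with the stage name.  Artifact files and their
    SHA-256 hashes are listed in ``manifest.json``; wall-clock timings go
    to ``run_log.json`` so the manifest is reproducible across reruns.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.echo(), "stages": []}
    timings = {}

    def stage(name):
        def wrap(fn):
            t0 = time.monotonic()
            try:
                files = fn()
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
            timings[name] = time.monotonic() - t0
            def _rel(p):
                try:
                    return str(Path(p).relative_to(outdir))
                except ValueError:
                    return str(p)

            manifest["stages"].append(
                {
                    "name": name,
                    "outputs": {
                        k: {"path": _rel(p), "sha256": _sha256(Path(p))}
                        for k, p in files.items()
                    },
                }
            )
            return files

        return wrap

    state: dict = {}

    # --- inputs -----------------------------------------------------------
    if config.synthetic_spec is not None:
        def _simulate():
            paths = synthetic.write_fixture_bundle(outdir / "synthetic", config.synthetic_spec)
            bundle = synthetic.read_fixture_bundle(outdir / "synthetic")
            state.update(bundle)
            return paths

        stage("simulate")(_simulate)
    else:
        def _load():
            ip = config.input_paths
            state["baseline"] = pd.read_csv(ip["baseline"], index_col=0)
            state["metadata"] = [
                preprocess.FeatureMetadata.from_dict(d)
                for d in json.loads(Path(ip["metadata"]).read_text())
            ]
            state["panel"] = pd.read_csv(ip["panel"])
            state["outcomes"] = pd.read_csv(ip["outcomes"])
            return {k: ip[k] for k in ("baseline", "metadata", "panel", "outcomes")}

        stage("load")(_load)

    # --- prepare ----------------------------------------------------------
    def _prepare():
        prepared, report = preprocess.prepare(state["baseline"], state["metadata"])
        state["prepared"] = prepared
        df = prepared.to_dataframe()
        df.index.name = "knee_id"
        p1 = outdir / "prepared_matrix.csv"
        df.to_csv(p1)
        p2 = outdir / "transform_log.json"
        p2.write_text(json.dumps(
            {
                "column_kinds": dict(zip(prepared.column_ids, prepared.column_kinds)),
                "transforms": {k: v.to_dict() for k, v in prepared.transform_log.items()},
                "complete_case_removed": report["complete_case"]["n_removed"],
            },
            indent=1,
        ))
        return {"prepared_matrix": p1, "transform_log": p2}

    stage("prepare")(_prepare)

    # --- bicluster --------------------------------------------------------
    def _bicluster():
        prepared = state["prepared"]
        bset = biclustering.find_exclusive_biclusters(
            prepared.values,
            delta=config.delta,
            max_k=config.max_k,
            min_rows=config.min_rows,
            row_ids=prepared.row_ids,
            col_ids=prepared.column_ids,
        )
        state["bicluster_set"] = bset
        p1 = outdir / "biclusters.json"
        p1.write_text(json.dumps(bset.to_dict(), indent=1))
        member = pd.DataFrame(
            {"knee_id": prepared.row_ids, "bicluster": bset.membership() + 1}
        )  # 0 encodes unassigned in the CSV
        p2 = outdir / "bicluster_membership.csv"
        member.to_csv(p2, index=False)
        return {"biclusters": p1, "membership": p2}

    stage("bicluster")(_bicluster)

    # --- sigclust ---------------------------------------------------------
    def _sigclust():
        bset = state["bicluster_set"]
        files = {}
        if len(bset) >= 2:
            results = sigclust.pairwise_sigclust(
                state["prepared"].values,
                bset,
                n_sim=config.sigclust_n_sim,
                seed=config.sigclust_seed,
                restarts=config.sigclust_restarts,
            )
            state["sigclust_results"] = results
            table = sigclust.results_table(results)
            p1 = outdir / "sigclust_pairs.csv"
            table.to_csv(p1, index=False)
            files["pairs"] = p1
            coords_rows = []
            for r in results:
                a, b = r.pair
                rows_a = list(bset.biclusters[a - 1].rows)
                rows_b = list(bset.biclusters[b - 1].rows)
                data = state["prepared"].values[rows_a + rows_b]
                labels = np.array([a] * len(rows_a) + [b] * len(rows_b))
                coords, _ = sigclust.mean_difference_projection(data, labels)
                for (x, y), lab, idx in zip(coords, labels, rows_a + rows_b):
                    coords_rows.append(
                        {"pair": f"{a}-{b}", "bicluster": lab, "row": idx,
                         "mean_diff": x, "ortho_pc1": y}
                    )
            p2 = outdir / "sigclust_projections.csv"
            pd.DataFrame(coords_rows).to_csv(p2, index=False)
            files["projections"] = p2
        else:
            state["sigclust_results"] = []
            p1 = outdir / "sigclust_pairs.csv"
            pd.DataFrame().to_csv(p1, index=False)
            files["pairs"] = p1
        return files

    stage("sigclust")(_sigclust)

    # --- trajectories -----------------------------------------------------
    def _trajectories():
        model = trajectory.select_model(
            state["panel"],
            G_max=config.gbtm_G_max,
            seed=config.gbtm_seed,
            dropout=config.gbtm_dropout,
            n_starts=config.gbtm_n_starts,
        )
        state["gbtm_model"] = model
        assign = trajectory.posterior_assign(model, state["panel"])
        state["traj_assignment"] = assign
        p1 = outdir / "gbtm_model.json"
        d = model.to_dict()
        d["group_proportion_ci"] = trajectory.group_proportion_ci(model)
        p1.write_text(json.dumps(d, indent=1))
        p2 = outdir / "posteriors.csv"
        assign.to_dataframe().to_csv(p2)
        return {"model": p1, "posteriors": p2}

    stage("trajectories")(_trajectories)

    # --- outcomes ---------------------------------------------------------
    def _outcomes():
        assign = state["traj_assignment"]
        traj_map = dict(zip(assign.knee_ids, (assign.assigned_group + 1).tolist()))
        knee_out = outcomes.compute_knee_outcomes(state["outcomes"], traj_map)
        state["knee_outcomes"] = knee_out
        prepared = state["prepared"]
        bset = state["bicluster_set"]
        labels = bset.membership() + 1
        membership = pd.Series(
            [lab if lab > 0 else "na" for lab in labels], index=prepared.row_ids
        )
        membership = membership[membership.index.isin(knee_out.index)]
        summary = outcomes.crosstab_bicluster_outcomes(membership, knee_out)
        state["outcome_summary"] = summary
        p1 = outdir / "knee_outcomes.csv"
        knee_out.to_csv(p1)
        p2 = outdir / "outcome_summary.json"
        p2.write_text(json.dumps(
            {
                "roa_proportions": json.loads(summary.roa_proportions.to_json()),
                "tka_rate": json.loads(summary.tka_rate.to_json()),
                "loss_quartiles": json.loads(summary.loss_quartiles.to_json()),
                "traj_proportions": json.loads(summary.traj_proportions.to_json()),
                "counts": json.loads(summary.counts.to_json()),
            },
            indent=1,
        ))
        return {"knee_outcomes": p1, "summary": p2}

    stage("outcomes")(_outcomes)

    # --- report -----------------------------------------------------------
    if config.figures:
        def _report():
            return render_reports(state, outdir)

        stage("report")(_report)

    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (outdir / "run_log.json").write_text(json.dumps({"timings_sec": timings}, indent=1))
    manifest["manifest_path"] = str(mpath)
    manifest["state"] = state  # in-memory handle for callers; not serialized
    return manifest


def load_state(outdir) -> dict:
    """Rebuild the in-memory stage state from a completed run's artifacts.

    Enough for :func:`render_reports`; component-likelihood matrices and
    other fit internals are not round-tripped.
    """
    outdir = Path(outdir)
    state: dict = {}
    df = pd.read_csv(outdir / "prepared_matrix.csv", index_col="knee_id")
    tlog = json.loads((outdir / "transform_log.json").read_text())
    state["prepared"] = preprocess.PreparedMatrix(
        values=df.to_numpy(dtype=float),
        row_ids=list(df.index),
        column_ids=list(df.columns),
        column_kinds=[tlog["column_kinds"][c] for c in df.columns],
    )
    state["bicluster_set"] = biclustering.BiclusterSet.from_dict(
        json.loads((outdir / "biclusters.json").read_text())
    )
    pairs_path = outdir / "sigclust_pairs.csv"
    results = []
    if pairs_path.exists():
        tbl = pd.read_csv(pairs_path)
        for _, r in tbl.iterrows():
            results.append(
                sigclust.SigClustResult(
                    pair=(int(r["bicluster_a"]), int(r["bicluster_b"])),
                    ci_observed=r["ci_observed"], null_mean=r["null_mean"],
                    null_sd=r["null_sd"], z=r["z"], p_normal=r["p_normal"],
                    p_empirical=r["p_empirical"], n_sim=int(r["n_sim"]),
                    seed=int(r["seed"]),
                )
            )
    state["sigclust_results"] = results
    model_path = outdir / "gbtm_model.json"
    if model_path.exists():
        d = json.loads(model_path.read_text())
        state["gbtm_model"] = trajectory.GbtmModel(
            G=d["G"], beta=[np.asarray(b) for b in d["beta"]],
            sigma=d["sigma"], pi=np.asarray(d["pi"]),
            dropout_coef=d["dropout_coef"], loglik=d["loglik"], bic=d["bic"],
            n_knees=d["n_knees"], converged=d["converged"], n_iter=d["n_iter"],
        )
    summary_path = outdir / "outcome_summary.json"
    if summary_path.exists():
        d = json.loads(summary_path.read_text())
        state["outcome_summary"] = outcomes.OutcomeSummary(
            roa_proportions=pd.DataFrame(d["roa_proportions"]),
            tka_rate=pd.Series(d["tka_rate"]),
            loss_quartiles=pd.DataFrame(d["loss_quartiles"]),
            traj_proportions=pd.DataFrame(d["traj_proportions"]),
            counts=pd.Series(d["counts"]),
        )
    return state


def render_reports(state: dict, outdir) -> dict:
    """Render the figure set (heatmap, comparisons, projections, outcome
    panels, trajectories); each figure gets a CSV twin with its data."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)
    files = {}
    prepared = state["prepared"]
    bset = state["bicluster_set"]
    member = bset.membership()

    # heatmap: knees ordered by bicluster along x, features on y
    order = np.argsort(np.where(member < 0, len(bset) + 1, member), kind="stable")
    fig, ax = plt.subplots(figsize=(10, 6))
    ax.imshow(
        prepared.values[order].T, aspect="auto", cmap="RdBu_r", vmin=-2, vmax=2,
        interpolation="nearest",
    )
    ticks, labels = [], []
    pos = 0
    for k, bc in enumerate(bset.biclusters):
        ticks.append(pos + bc.n_rows / 2)
        labels.append(str(k + 1))
        pos += bc.n_rows
    if len(bset.unassigned_rows):
        ticks.append(pos + len(bset.unassigned_rows) / 2)
        labels.append("na")
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("knees (grouped by bicluster)")
    ax.set_ylabel("features")
    p = figdir / "bicluster_heatmap.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    files["heatmap"] = p
    twin = outdir / "figures" / "bicluster_heatmap.csv"
    pd.DataFrame(
        {"knee_order": order, "bicluster": member[order] + 1}
    ).to_csv(twin, index=False)
    files["heatmap_csv"] = twin

    # standardized boxplots per bicluster for the most contrasting features
    cont = [j for j, k in enumerate(prepared.column_kinds)
            if k == preprocess.STD_CONTINUOUS][:8]
    if cont and len(bset):
        fig, ax = plt.subplots(figsize=(10, 4))
        data, labels_bp = [], []
        rows_box = []
        for j in cont:
            for k, bc in enumerate(bset.biclusters):
                if j in bc.cols:
                    vals = prepared.values[list(bc.rows), j]
                    data.append(vals)
                    labels_bp.append(f"{prepared.column_ids[j]}\n#{k + 1}")
                    q = np.percentile(vals, [25, 50, 75])
                    rows_box.append({"feature": prepared.column_ids[j],
                                     "bicluster": k + 1, "q25": q[0],
                                     "q50": q[1], "q75": q[2]})
        if data:
            ax.boxplot(data[:24], tick_labels=labels_bp[:24], showfliers=False)
            ax.tick_params(axis="x", labelsize=6, rotation=90)
            ax.axhline(0.0, color="gray", lw=0.6)
            ax.set_ylabel("standardized value")
            p = figdir / "feature_boxplots.png"
            fig.savefig(p, dpi=110, bbox_inches="tight")
            files["boxplots"] = p
            twin = figdir / "feature_boxplots.csv"
            pd.DataFrame(rows_box).to_csv(twin, index=False)
            files["boxplots_csv"] = twin
        plt.close(fig)

    # sigclust projection panel
    results = state.get("sigclust_results") or []
    if results:
        ncol = min(5, len(results))
        nrow = int(np.ceil(len(results) / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 3 * nrow), squeeze=False)
        for ax in axes.ravel():
            ax.axis("off")
        for i, r in enumerate(results):
            a, b = r.pair
            rows_a = list(bset.biclusters[a - 1].rows)
            rows_b = list(bset.biclusters[b - 1].rows)
            data = prepared.values[rows_a + rows_b]
            labels_pr = np.array([0] * len(rows_a) + [1] * len(rows_b))
            coords, _ = sigclust.mean_difference_projection(data, labels_pr)
            ax = axes.ravel()[i]
            ax.axis("on")
            for lab, color in ((0, "tab:blue"), (1, "tab:orange")):
                m = labels_pr == lab
                ax.scatter(coords[m, 0], coords[m, 1], s=4, color=color, alpha=0.5)
            ax.set_title(f"#{a} vs #{b}", fontsize=8)
            ax.text(
                0.05, 0.92, f"z={r.z:.1f}",
                transform=ax.transAxes, fontsize=8,
                color="red" if r.significant else "black",
            )
        p = figdir / "sigclust_projections.png"
        fig.savefig(p, dpi=110, bbox_inches="tight")
        plt.close(fig)
        files["sigclust_panel"] = p

    # outcome bars + loss boxplots
    summary = state.get("outcome_summary")
    if summary is not None:
        fig, axes = plt.subplots(1, 2, figsize=(11, 4))
        summary.roa_proportions.plot.bar(stacked=True, ax=axes[0], legend=True)
        axes[0].set_ylabel("proportion")
        axes[0].set_title("radiographic outcome by bicluster")
        summary.tka_rate.plot.bar(ax=axes[1], color="tab:red")
        axes[1].set_ylabel("TKA rate")
        p = figdir / "outcome_bars.png"
        fig.savefig(p, dpi=110, bbox_inches="tight")
        plt.close(fig)
        files["outcome_bars"] = p
        twin = figdir / "outcome_bars.csv"
        summary.roa_proportions.assign(tka_rate=summary.tka_rate).to_csv(twin)
        files["outcome_bars_csv"] = twin
        twin = figdir / "loss_quartiles.csv"
        summary.loss_quartiles.to_csv(twin)
        files["loss_quartiles_csv"] = twin

    # trajectory means + stacked assignment bars
    model = state.get("gbtm_model")
    if model is not None:
        fig, axes = plt.subplots(1, 2, figsize=(11, 4))
        months = np.array(trajectory.ALL_MONTHS, dtype=float)
        rows_tr = []
        for g in range(model.G):
            mean = np.concatenate([[0.0], model.mean_trajectory(g)])
            axes[0].plot(months, mean, marker="o",
                         label=f"group {g + 1} ({model.pi[g]:.1%})")
            for m, v in zip(months, mean):
                rows_tr.append({"group": g + 1, "month": m, "mean_change": v})
        axes[0].set_xlabel("month")
        axes[0].set_ylabel("mean pain change")
        axes[0].legend(fontsize=7)
        if summary is not None and len(summary.traj_proportions.columns):
            summary.traj_proportions.plot.barh(stacked=True, ax=axes[1], legend=True)
            axes[1].set_xlabel("proportion of knees")
        p = figdir / "trajectories.png"
        fig.savefig(p, dpi=110, bbox_inches="tight")
        plt.close(fig)
        files["trajectories"] = p
        twin = figdir / "trajectories.csv"
        pd.DataFrame(rows_tr).to_csv(twin, index=False)
        files["trajectories_csv"] = twin

    return files
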