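"""End-to-end pipeline: simulate/load -> normalize -> DE -> cluster -> enrich.

``run_pipeline`` executes the full analysis deterministically for a given
seed and writes a result bundle: PCA report, normalized matrix, per-contrast
differential-expression tables, call summaries, overlap tables (with up/down
split), dendrogram (Newick + merge table), enrichment clusters, a generated
README describing every output, and a manifest (config hash, versions, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import cluster_conditions, condition_means, replicate_silhouette
from .dex import (
    DEFAULT_CONTRASTS,
    DEFAULT_FDR_THRESHOLDS,
    Contrast,
    call_de,
    overlap_test,
    run_contrast,
)
from .enrich import cluster_enrichment, read_gmt
from .errors import ConfigurationError, StageError
from .matrix import read_matrix, write_annotations, write_matrix
from .normalize import compute_pca, pca_report, remove_components, standardize_genes
from .synthdata import SimConfig, generate_dataset, write_truth

log = logging.getLogger("uvdex")


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML/JSON."""

    matrix_path: str | None = None
    annotations_path: str | None = None
    gmt_path: str | None = None
    sim: SimConfig | None = None
    k_remove: int = 1
    scale: bool = False
    contrasts: tuple = tuple((c.treatment, c.control) for c in DEFAULT_CONTRASTS)
    fdr_thresholds: tuple = DEFAULT_FDR_THRESHOLDS
    null_method: str = "central-matching"
    cluster_metric: str = "centered"
    overlap_pairs: tuple = (("FC30'", "RT30'"),)
    kappa_threshold: float = 0.3
    min_membership: int = 4
    min_overlap: int = 3
    enrichment_max_p: float = 0.05
    ease: bool = True
    make_plots: bool = True
    outdir: str = "uvdex_results"
    seed: int = 0

    def validate(self):
        if (self.matrix_path is None) == (self.sim is None):
            raise ConfigurationError(
                "exactly one of matrix_path or sim must be provided"
            )
        for thr in self.fdr_thresholds:
            if not 0 < thr < 1:
                raise ConfigurationError("fdr_thresholds must lie in (0, 1)")
        if self.k_remove < 0:
            raise ConfigurationError("k_remove must be >= 0")

    # -- serialization ---------------------------------------------------------

    def to_dict(self) -> dict:
        # outdir excluded: result bundles are reproducible regardless of
        # where they are written
        d = dataclasses.asdict(self)
        d.pop("outdir", None)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("sim") is not None:
            from .synthdata import CircadianSpec, EffectSpec, FactorSpec

            s = dict(d["sim"])
            s["factors"] = [FactorSpec(**dict(f)) for f in s.get("factors", [])]
            if s.get("circadian") is not None:
                s["circadian"] = CircadianSpec(**dict(s["circadian"]))
            s["effects"] = [
                EffectSpec(**{**dict(e),
                              "log2fc_range": tuple(e["log2fc_range"])})
                for e in s.get("effects", [])
            ]
            s["design"] = [tuple(row) for row in s.get("design", [])]
            d["sim"] = SimConfig(**s)
        for key in ("contrasts", "overlap_pairs"):
            if key in d and d[key] is not None:
                d[key] = tuple(tuple(x) for x in d[key])
        if "fdr_thresholds" in d:
            d["fdr_thresholds"] = tuple(d["fdr_thresholds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh,
                           sort_keys=True)


BUNDLE_README = """\
# uvdex result bundle

| file | contents |
| --- | --- |
| manifest.json | config hash, package/library versions, seed |
| config.yaml | the resolved run configuration |
| matrix.tsv / annotations.tsv / truth.tsv | simulated inputs (simulate mode only) |
| pca_report.tsv | per-component singular value and variance fraction |
| sample_loadings.tsv / gene_scores.tsv | PCA loadings (samples) and scores (genes) |
| normalized_matrix.tsv | standardized matrix after removing the top-k components |
| de_<contrast>.tsv | per-gene t, df, log2fc, z, lfdr, bh_q, direction, calls |
| call_summary.tsv | up/down call counts per contrast and fdr threshold |
| overlap.tsv | called-gene overlap between contrast pairs, split up/down |
| dendrogram.nwk / merge_table.tsv | condition-profile average-linkage clustering |
| replicate_silhouette.txt | silhouette of replicates under condition labels |
| enrichment_<contrast>_<dir>.tsv | annotation clusters with EASE scores |
| pca_loadings.png / dendrogram.png | basic figures (when plots enabled) |
"""


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages and write the result bundle; returns the bundle path.

    Deterministic given the seed.  On stage failure the partially written
    outputs are renamed with a ``.partial`` suffix and a
    :class:`StageError` naming the stage is raised.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str) -> Path:
        p = out / name
        written.append(p)
        return p

    stage = "setup"
    try:
        config.to_yaml(emit("config.yaml"))
        manifest = {
            "config_sha256": hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
            ).hexdigest(),
            "seed": config.seed,
            "uvdex_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
        }
        with open(emit("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        (out / "README.md").write_text(BUNDLE_README)
        written.append(out / "README.md")

        stage = "input"
        if config.sim is not None:
            log.info("simulating dataset (seed=%s)", config.sim.seed)
            X, truth = generate_dataset(config.sim)
            write_matrix(X, emit("matrix.tsv"))
            write_annotations(X, emit("annotations.tsv"))
            write_truth(truth, emit("truth.tsv"))
        else:
            log.info("reading matrix from %s", config.matrix_path)
            X = read_matrix(config.matrix_path, config.annotations_path)

        stage = "normalize"
        Xs = standardize_genes(X, scale=config.scale)
        model = compute_pca(Xs)
        pca_report(model).to_csv(emit("pca_report.tsv"), sep="\t", index=False,
                                 float_format="%.6g")
        model.sample_loadings.to_csv(emit("sample_loadings.tsv"), sep="\t",
                                     float_format="%.6g")
        model.gene_scores.to_csv(emit("gene_scores.tsv"), sep="\t",
                                 float_format="%.6g")
        log.info(
            "top-3 variance fractions: %s",
            np.round(model.variance_fractions[:3], 3),
        )
        Xn = remove_components(Xs, model, config.k_remove)
        write_matrix(Xn, emit("normalized_matrix.tsv"))
        if config.make_plots:
            _plot_loadings(model, Xs, emit("pca_loadings.png"))

        stage = "differential-expression"
        contrasts = [Contrast(t, c) for t, c in config.contrasts]
        results = {}
        if not contrasts:
            log.warning("no contrasts configured; skipping differential "
                        "expression and overlap stages")
        summary_rows = []
        for c in contrasts:
            res, null, _ = run_contrast(
                Xn, c, null_method=config.null_method,
                thresholds=config.fdr_thresholds,
            )
            results[c.treatment] = res
            fn = f"de_{c.treatment}_vs_{c.control}.tsv".replace("'", "")
            res.to_csv(emit(fn), sep="\t", float_format="%.6g",
                       index_label="gene")
            log.info(
                "%s: null=(%.3f, %.3f, pi0=%.3f)",
                c, null.delta0, null.sigma0, null.pi0,
            )
            for thr in config.fdr_thresholds:
                up, down = call_de(res, thr)
                summary_rows.append((str(c), thr, len(up), len(down)))
        if contrasts:
            pd.DataFrame(
                summary_rows, columns=["contrast", "fdr", "n_up", "n_down"]
            ).to_csv(emit("call_summary.tsv"), sep="\t", index=False)

        stage = "overlap"
        if contrasts:
            universe = set(Xn.gene_ids)
            rows = []
            for a, b in config.overlap_pairs:
                if a not in results or b not in results:
                    continue
                for thr in config.fdr_thresholds:
                    up_a, down_a = call_de(results[a], thr)
                    up_b, down_b = call_de(results[b], thr)
                    for direction, sa, sb in (
                        ("up", up_a, up_b), ("down", down_a, down_b)
                    ):
                        k, p = overlap_test(sa, sb, universe)
                        rows.append((a, b, thr, direction, len(sa), len(sb), k, p))
            pd.DataFrame(
                rows,
                columns=["contrast_a", "contrast_b", "fdr", "direction",
                         "n_a", "n_b", "overlap", "hypergeom_p"],
            ).to_csv(emit("overlap.tsv"), sep="\t", index=False,
                     float_format="%.4g")

        stage = "clustering"
        profiles = condition_means(Xn)
        dendro = cluster_conditions(profiles, metric=config.cluster_metric)
        emit("dendrogram.nwk").write_text(dendro.to_newick() + "\n")
        dendro.merge_table().to_csv(emit("merge_table.tsv"), sep="\t",
                                    index=False, float_format="%.6g")
        sil = replicate_silhouette(Xs, metric=config.cluster_metric)
        emit("replicate_silhouette.txt").write_text(f"{sil:.6f}\n")
        if config.make_plots:
            _plot_dendrogram(dendro, emit("dendrogram.png"))

        stage = "enrichment"
        if config.gmt_path is not None and contrasts:
            collection = read_gmt(config.gmt_path)
            universe = set(Xn.gene_ids)
            thr = max(config.fdr_thresholds)
            for c in contrasts:
                up, down = call_de(results[c.treatment], thr)
                for direction, genes in (("up", up), ("down", down)):
                    clusters = cluster_enrichment(
                        genes, collection, universe,
                        min_overlap=config.min_overlap,
                        max_p=config.enrichment_max_p,
                        kappa_threshold=config.kappa_threshold,
                        min_membership=config.min_membership,
                        ease=config.ease,
                    )
                    fn = (f"enrichment_{c.treatment}_{direction}.tsv"
                          .replace("'", ""))
                    pd.DataFrame(
                        [
                            (i + 1, cl.ease_score, cl.enriched,
                             ";".join(cl.members))
                            for i, cl in enumerate(clusters)
                        ],
                        columns=["cluster", "ease_score", "enriched", "terms"],
                    ).to_csv(emit(fn), sep="\t", index=False,
                             float_format="%.4g")
    except Exception as exc:
        for p in written:
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        raise StageError(stage, str(exc)) from exc
    return out


def _plot_loadings(model, X, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    groups = X.samples["group"]
    for g in dict.fromkeys(groups):
        sel = (groups == g).to_numpy()
        ax.scatter(
            model.sample_loadings.to_numpy()[sel, 0],
            model.sample_loadings.to_numpy()[sel, 1],
            label=g, s=18,
        )
    vf = model.variance_fractions
    ax.set_xlabel(f"PC1 loading ({vf[0]:.0%})")
    ax.set_ylabel(f"PC2 loading ({vf[1]:.0%})")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_dendrogram(dendro, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

    fig, ax = plt.subplots(figsize=(5, 4))
    scipy_dendrogram(dendro.linkage, labels=dendro.labels, ax=ax,
                     color_threshold=0.0)
    ax.set_ylabel("1 - correlation (average linkage)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
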