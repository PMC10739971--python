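"""End-to-end orchestration of the four pipeline stages.

Supervised mode builds the manifold outline from target or output vectors
and uses its bins as pseudo-labels for the Bayesian projection;
unsupervised mode builds the outline from the input features themselves.
Colors always come from the target manifold when targets are provided.
A single seed drives independent derived streams for the projection
sampler and the embedding optimizer.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, fields

import numpy as np

from . import embedding as emb
from . import evaluation as ev
from . import io as mio
from . import outline as ol
from . import projection as pr

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "write_results", "plot_embedding"]

log = logging.getLogger("mda")


class PipelineError(ValueError):
    """Invalid pipeline inputs or configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Settings for a full run; defaults are the method's standard settings
    (R = 16, 200 projection iterations, a = b = 1, k = 30 embedding
    neighbours, learning rate 0.001, all gamma scale parameters 1)."""

    mode: str = "supervised"
    R: int = 16
    max_iter: int = 200
    tol: float = 1e-4
    mc_samples: int = 200
    k_graph: int = 10
    a: float = 1.0
    b: float = 1.0
    k: int = 30
    lr: float = 0.001
    epochs: int = 200
    neg_samples: int = 5
    seed: int = 0
    standardize: bool = True

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        """Parse a ``key = value`` text file into a RunConfig."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#")[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise PipelineError(f"{path}:{lineno}: expected key = value")
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in known:
                    raise PipelineError(f"{path}:{lineno}: unknown key {key!r}")
                default = getattr(cls, key)
                if isinstance(default, bool):
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                elif isinstance(default, int):
                    kwargs[key] = int(value)
                elif isinstance(default, float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)


@dataclass(frozen=True)
class PipelineResult:
    outline: ol.OutlineModel
    color_outline: ol.OutlineModel
    state: pr.VariationalState
    projection: pr.Projection
    embedding: emb.EmbeddingModel
    metrics: ev.MetricReport


def _derived_seeds(seed: int, n: int = 2) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % 2**31) for s in state]


def run_pipeline(
    features: np.ndarray,
    targets: np.ndarray | None = None,
    outputs: np.ndarray | None = None,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run outline -> projection -> embedding -> evaluation.

    Parameters
    ----------
    features : ndarray (n_samples, n_features)
        The data to project and embed (sample-major).
    targets : ndarray, optional
        Target/label vectors; define the color manifold and, in the
        absence of ``outputs``, the pseudo-label outline.
    outputs : ndarray, optional
        Model-output vectors; when given, pseudo-labels come from these.
    config : RunConfig
    """
    config = config or RunConfig()
    if config.mode not in ("supervised", "unsupervised"):
        raise PipelineError(f"unknown mode {config.mode!r}")
    features = np.atleast_2d(np.asarray(features, dtype=float))
    n = features.shape[0]

    def _check(name, arr):
        if arr is None:
            return None
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape[0] != n:
            raise PipelineError(
                f"{name} has {arr.shape[0]} samples but features has {n}"
            )
        return arr

    targets = _check("targets", targets)
    outputs = _check("outputs", outputs)

    t0 = time.perf_counter()
    if config.mode == "supervised":
        label_src, src_mode = (
            (outputs, "outputs") if outputs is not None else (targets, "targets")
        )
        if label_src is None:
            raise PipelineError("supervised mode requires targets or outputs")
        outline = ol.build_outline(label_src, mode=src_mode, k_graph=config.k_graph)
    else:
        outline = ol.build_outline(features, mode="inputs", k_graph=config.k_graph)

    if targets is not None:
        if config.mode == "supervised" and outputs is None:
            color_outline = outline  # same source, reuse
        else:
            color_outline = ol.build_outline(
                targets, mode="targets", k_graph=config.k_graph
            )
    else:
        color_outline = outline
    log.info("outline: K=%d bins, endpoint=%d (%.2fs)",
             outline.K, outline.endpoint, time.perf_counter() - t0)

    seeds = _derived_seeds(config.seed)
    t0 = time.perf_counter()
    hyper = pr.Hyperparams(
        R=config.R, max_iter=config.max_iter, tol=config.tol,
        mc_samples=config.mc_samples, seed=seeds[0],
    )
    state, proj = pr.fit(
        features.T, outline.pseudo_labels, hyper, standardize=config.standardize
    )
    log.info("projection: U is %s (%.2fs)", proj.U.shape, time.perf_counter() - t0)

    t0 = time.perf_counter()
    k_embed = min(config.k, n - 1)
    graph = emb.build_fuzzy_graph(proj.U, k=k_embed)
    econf = emb.EmbeddingConfig(
        a=config.a, b=config.b, k=k_embed, lr=config.lr,
        epochs=config.epochs, neg_samples=config.neg_samples, seed=seeds[1],
    )
    model = emb.fit_embedding(proj.U, graph, econf)
    log.info("embedding: final loss %.4f (%.2fs)",
             model.loss_history[-1], time.perf_counter() - t0)

    t0 = time.perf_counter()
    pear = ev.pearson_geodesic(features, model.V, k_graph=config.k_graph)
    dem = ev.demap(features, model.V, k_graph=config.k_graph)
    try:
        knn = ev.knn_accuracy(model.V, outline.pseudo_labels, seed=config.seed)
    except ev.EvaluationError:
        knn = None
    metrics = ev.MetricReport(
        pearson_geodesic=pear, demap=dem, knn_accuracy=knn,
        k_graph=config.k_graph, seed=config.seed,
    )
    log.info("evaluation: pearson=%.3f demap=%.3f (%.2fs)",
             pear, dem, time.perf_counter() - t0)
    return PipelineResult(
        outline=outline, color_outline=color_outline, state=state,
        projection=proj, embedding=model, metrics=metrics,
    )


def write_results(result: PipelineResult, outdir: str, sample_ids=None) -> None:
    """Write all artifacts (outline, U, mu_Q, embedding, metrics) as TSV."""
    import os

    os.makedirs(outdir, exist_ok=True)
    mio.write_outline(os.path.join(outdir, "outline.tsv"),
                      result.color_outline, sample_ids)
    mio.write_projection(os.path.join(outdir, "projection_U.tsv"),
                         result.projection,
                         os.path.join(outdir, "projection_muQ.tsv"))
    mio.write_embedding(os.path.join(outdir, "embedding.tsv"),
                        result.embedding, result.color_outline, sample_ids)
    mio.write_metrics(os.path.join(outdir, "metrics.tsv"), result.metrics)


def plot_embedding(result: PipelineResult, path: str) -> None:
    """Scatter of V colored by normalized manifold distance (red = start,
    violet = end)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(
        result.embedding.V[:, 0], result.embedding.V[:, 1],
        c=result.color_outline.color, cmap="rainbow_r", s=12,
    )
    fig.colorbar(sc, ax=ax, label="normalized manifold distance")
    ax.set_xlabel("v1")
    ax.set_ylabel("v2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
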