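"""Configuration containers for the random-walk engine and the pipeline."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ParameterError


@dataclass
class WalkConfig:
    """Parameters of the lazy-teleporting random walk.

    Attributes
    ----------
    x:
        Retention probability of the lazy walk: at each non-teleporting step
        the walker stays put with probability ``1 - x`` and otherwise moves
        to a neighbour.  Must lie in ``(0, 1]``.
    alpha:
        Teleport retention probability: with probability ``1 - alpha`` the
        walker relocates uniformly at random over all nodes.  Must lie in
        ``(0, 1]``; the closed-form hitting times additionally require
        ``alpha < 1``.
    b:
        Growth factor of the logistic edge-bias function (default 1).
    n_mcmc:
        Number of simulated walks per Monte-Carlo estimate.
    max_steps:
        Cap on the number of steps per walk.  ``None`` means
        ``1000 * n_nodes``, resolved when a walk is run.
    seed:
        Integer seed threaded through every stochastic stage.
    """

    x: float = 0.95
    alpha: float = 0.99
    b: float = 1.0
    n_mcmc: int = 1000
    max_steps: int | None = None
    seed: int = 42

    def __post_init__(self) -> None:
        if not (0.0 < self.x <= 1.0):
            raise ParameterError(f"laziness retention x must be in (0, 1], got {self.x}")
        if not (0.0 < self.alpha <= 1.0):
            raise ParameterError(f"teleport retention alpha must be in (0, 1], got {self.alpha}")
        if self.b <= 0:
            raise ParameterError(f"logistic growth factor b must be positive, got {self.b}")
        if self.n_mcmc < 1:
            raise ParameterError(f"n_mcmc must be >= 1, got {self.n_mcmc}")
        if self.max_steps is not None and self.max_steps < 1:
            raise ParameterError(f"max_steps must be >= 1, got {self.max_steps}")

    def resolve_max_steps(self, n_nodes: int) -> int:
        return self.max_steps if self.max_steps is not None else 1000 * n_nodes


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (mirrors the ``trajwalk infer`` flags)."""

    input_path: str | Path = ""
    input_format: str | None = None  # csv / tsv / mtx / h5ad, None = infer
    log1p: bool = True
    n_pcs: int = 10
    knn: int = 20
    metric: str = "euclidean"
    clustering: str = "community_detection"  # or "kmeans"
    resolution: float = 1.0
    kmeans_k: int = 10
    root_mode: str = "cluster_id"  # cell_index / group_label / cluster_id
    root_value: str | int = 0
    annotations_path: str | Path | None = None
    x: float = 0.95
    alpha: float = 0.99
    b: float = 1.0
    n_mcmc: int = 1000
    max_steps: int | None = None
    time_scale: float = 10.0
    n_smooth: int = 1
    t_steps: int = 3
    trend_features: list[str] = field(default_factory=list)
    outdir: str | Path = "trajwalk_out"
    seed: int = 42
    verbosity: int = 1

    def walk_config(self) -> WalkConfig:
        return WalkConfig(
            x=self.x, alpha=self.alpha, b=self.b,
            n_mcmc=self.n_mcmc, max_steps=self.max_steps, seed=self.seed,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["input_path"] = str(d["input_path"])
        d["outdir"] = str(d["outdir"])
        if d["annotations_path"] is not None:
            d["annotations_path"] = str(d["annotations_path"])
        return d

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))
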