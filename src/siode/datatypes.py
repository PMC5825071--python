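"""Shared data containers for the single-index ODE pipeline.

Lightweight dataclasses carry data between the pipeline stages:
expression matrices into clustering, module curves and derivatives
(a :class:`StateSet`) into the ODE model fits, and simulated
trajectories out of the benchmark system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ModuleAssignment",
    "TrajectorySet",
    "StateSet",
]


@dataclass
class ExpressionMatrix:
    """Genes x timepoints expression observations on a shared time grid.

    Parameters
    ----------
    gene_ids : list of str
        One identifier per row of ``values``.
    times : ndarray, shape (T,)
        Strictly increasing observation times shared by all genes.
    values : ndarray, shape (n_genes, T)
        Expression levels; finite after the NA policy has been applied.
    """

    gene_ids: list
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x timepoints)")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length does not match values rows")
        if self.times.shape[0] != self.values.shape[1]:
            raise ValueError("times length does not match values columns")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_tsv(cls, path, max_na_fraction: float = 0.5) -> "ExpressionMatrix":
        """Read the expression TSV dialect: header ``gene <t1> <t2> ...``,
        one row per gene, ``NA`` for missing values.

        Rows with more than ``max_na_fraction`` missing are rejected;
        remaining missing values are linearly interpolated in time.
        """
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        times = np.asarray([float(c) for c in df.columns[1:]])
        gene_ids = df.iloc[:, 0].astype(str).tolist()
        values = df.iloc[:, 1:].to_numpy(dtype=float)
        na_frac = np.isnan(values).mean(axis=1)
        bad = na_frac > max_na_fraction
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} gene rows exceed the {max_na_fraction:.0%} "
                "missing-value limit: " + ", ".join(np.asarray(gene_ids)[bad][:5])
            )
        for i in range(values.shape[0]):
            miss = np.isnan(values[i])
            if miss.any():
                values[i, miss] = np.interp(times[miss], times[~miss], values[i, ~miss])
        return cls(gene_ids=gene_ids, times=times, values=values)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=[f"{t:.10g}" for t in self.times])
        df.insert(0, "gene", self.gene_ids)
        df.to_csv(path, sep="\t", index=False)


@dataclass
class ModuleAssignment:
    """Gene-to-module labels with the mixture quantities behind them.

    ``responsibilities`` rows sum to one; ``labels`` is their argmax.
    ``mean_curves`` holds the K cluster mean curves evaluated on the
    observation times; ``noise_variances`` the per-cluster iid noise
    variance.  ``bic_by_k`` records the model-selection trace.
    """

    labels: np.ndarray
    responsibilities: np.ndarray
    mean_curves: np.ndarray
    noise_variances: np.ndarray
    k_selected: int
    bic_by_k: dict = field(default_factory=dict)
    gene_ids: list | None = None

    @property
    def mixing_proportions(self) -> np.ndarray:
        return self.responsibilities.mean(axis=0)

    def to_tsv(self, path) -> None:
        """Write ``gene, module, max_posterior`` columns (modules 1-based)."""
        ids = self.gene_ids or [f"g{i}" for i in range(len(self.labels))]
        df = pd.DataFrame(
            {
                "gene": ids,
                "module": self.labels + 1,
                "max_posterior": self.responsibilities.max(axis=1),
            }
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @staticmethod
    def labels_from_tsv(path) -> pd.DataFrame:
        """Read a precomputed ``gene, module`` assignment (module 1-based)."""
        df = pd.read_csv(path, sep="\t")
        if not {"gene", "module"}.issubset(df.columns):
            raise ValueError("assignment TSV needs 'gene' and 'module' columns")
        return df


@dataclass
class TrajectorySet:
    """One numerically integrated trajectory of the benchmark system."""

    grid: np.ndarray
    states: np.ndarray
    replicate_id: int = 0
    seed_used: int | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        d = np.diff(self.grid)
        if np.any(d <= 0):
            raise ValueError("grid must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("states must be finite everywhere")

    def to_tsv(self, path) -> None:
        cols = {"time": self.grid}
        for p in range(self.states.shape[1]):
            cols[f"X{p + 1}"] = self.states[:, p]
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass
class StateSet:
    """Module state curves and target derivatives on an augmented grid.

    ``states[i, j]`` is module j's state X_j(t_i); ``derivatives[i, k]``
    is the spline estimate of dX_k/dt at t_i, the response of the k-th
    single-index ODE fit.
    """

    grid: np.ndarray
    states: np.ndarray
    derivatives: np.ndarray
    module_names: list | None = None
    boundary_flags: np.ndarray | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        self.derivatives = np.asarray(self.derivatives, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if not (np.all(np.isfinite(self.states)) and np.all(np.isfinite(self.derivatives))):
            raise ValueError("states and derivatives must be finite")
        if self.states.shape != self.derivatives.shape:
            raise ValueError("states and derivatives must share a shape")
        if self.states.shape[0] != self.grid.shape[0]:
            raise ValueError("row count must equal grid length")

    @property
    def n_modules(self) -> int:
        return self.states.shape[1]

    def to_tsv(self, path) -> None:
        names = self.module_names or [str(j + 1) for j in range(self.n_modules)]
        cols = {"time": self.grid}
        for j, nm in enumerate(names):
            cols[f"X_{nm}"] = self.states[:, j]
        for j, nm in enumerate(names):
            cols[f"dX_{nm}"] = self.derivatives[:, j]
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "StateSet":
        df = pd.read_csv(path, sep="\t")
        xcols = [c for c in df.columns if c.startswith("X_")]
        dcols = [c for c in df.columns if c.startswith("dX_")]
        names = [c[2:] for c in xcols]
        if [c[3:] for c in dcols] != names:
            raise ValueError("state and derivative columns do not match")
        return cls(
            grid=df["time"].to_numpy(),
            states=df[xcols].to_numpy(),
            derivatives=df[dcols].to_numpy(),
            module_names=names,
        )
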