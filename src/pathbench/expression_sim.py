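"""Simulation of case/control gene-expression matrices with planted signal.

Every gene (network node) gets one expression value per sample, drawn
independently from a normal distribution chosen by the (gene class, sample
class) cell:

Varying-mean model (VM)
    FG x case   ~ N(mu_fg, v)
    FG x control~ N(mu_fgc, v)
    BG x any    ~ N(0, v)            with v = 1 by default.
    Signal strength = mu_fg - mu_fgc (a location shift).

Varying-variance model (VV)
    FG x case   ~ N(mu, v_fg)
    FG x control~ N(mu, v_bg)        (control-FG shares the BG distribution)
    BG x any    ~ N(mu, v_bg)        with mu = 0 by default.
    Signal strength = v_fg / v_bg (a scale shift).

``v``-parameters are variances, not standard deviations. The default design
is 100 case and 10 control samples. Entries are independent across genes;
no gene-gene correlation structure is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .graph_io import InteractionNetwork
from .fg_selection import GoldStandardSplit

__all__ = [
    "SimulationConfig",
    "ExpressionDataset",
    "simulate_expression",
    "signal_strength",
    "differential_stats",
]

#: Default signal-strength grids swept in benchmarks, user-overridable.
DEFAULT_VM_GRID = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0)
DEFAULT_VV_GRID = (1.0, 2.0, 4.0, 8.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated expression dataset.

    Exactly the fields of the chosen model are meaningful: ``mu_fg``,
    ``mu_fgc`` and ``v`` for VM; ``mu``, ``v_fg`` and ``v_bg`` for VV.
    Setting a field of the other model raises at validation.
    """

    model: Literal["VM", "VV"]
    seed: int = 0
    n_cases: int = 100
    n_controls: int = 10
    # VM parameters
    mu_fg: float | None = None
    mu_fgc: float | None = None
    v: float | None = None
    # VV parameters
    mu: float | None = None
    v_fg: float | None = None
    v_bg: float | None = None

    def __post_init__(self) -> None:
        if self.model not in ("VM", "VV"):
            raise ValueError(f"model must be 'VM' or 'VV', got {self.model!r}")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be positive")
        if self.model == "VM":
            if self.mu_fg is None or self.mu_fgc is None:
                raise ValueError("VM requires mu_fg and mu_fgc")
            if self.v is None:
                object.__setattr__(self, "v", 1.0)
            if self.v <= 0:
                raise ValueError("variance v must be strictly positive")
            foreign = {"mu": self.mu, "v_fg": self.v_fg, "v_bg": self.v_bg}
        else:
            if self.v_fg is None or self.v_bg is None:
                raise ValueError("VV requires v_fg and v_bg")
            if self.v_fg <= 0 or self.v_bg <= 0:
                raise ValueError("variances v_fg and v_bg must be strictly positive")
            if self.mu is None:
                object.__setattr__(self, "mu", 0.0)
            foreign = {"mu_fg": self.mu_fg, "mu_fgc": self.mu_fgc, "v": self.v}
        bad = [name for name, value in foreign.items() if value is not None]
        if bad:
            raise ValueError(f"fields {bad} do not belong to the {self.model} model")

    @classmethod
    def vm(cls, mu_fg: float, mu_fgc: float = 0.0, v: float = 1.0, **kw) -> "SimulationConfig":
        return cls(model="VM", mu_fg=mu_fg, mu_fgc=mu_fgc, v=v, **kw)

    @classmethod
    def vv(cls, v_fg: float, v_bg: float = 1.0, mu: float = 0.0, **kw) -> "SimulationConfig":
        return cls(model="VV", v_fg=v_fg, v_bg=v_bg, mu=mu, **kw)

    @classmethod
    def from_signal_strength(
        cls, model: str, strength: float, seed: int = 0, **kw
    ) -> "SimulationConfig":
        """Build the canonical config realising a given signal strength.

        VM: ``mu_fgc = 0`` so ``mu_fg = strength``. VV: ``v_bg = 1`` so
        ``v_fg = strength`` (the variance ratio); a VV strength below 1 is
        rejected since FG variance is never smaller than BG variance here.
        """
        if model == "VM":
            return cls.vm(mu_fg=strength, mu_fgc=0.0, seed=seed, **kw)
        if model == "VV":
            if strength < 1:
                raise ValueError("VV signal strength (variance ratio) must be >= 1")
            return cls.vv(v_fg=strength, v_bg=1.0, seed=seed, **kw)
        raise ValueError(f"model must be 'VM' or 'VV', got {model!r}")


def signal_strength(config: SimulationConfig) -> float:
    """FG-vs-BG separation: ``mu_fg - mu_fgc`` (VM) or ``v_fg / v_bg`` (VV)."""
    if config.model == "VM":
        return config.mu_fg - config.mu_fgc
    return config.v_fg / config.v_bg


@dataclass(frozen=True)
class ExpressionDataset:
    """A genes x samples expression matrix with case/control labels.

    ``values`` is a :class:`pandas.DataFrame` with gene IDs as the index and
    sample IDs as columns; ``sample_labels`` gives each column's class
    (``"case"`` or ``"control"``) in column order.
    """

    values: pd.DataFrame
    sample_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sample_labels) != self.values.shape[1]:
            raise ValueError("one label per sample column is required")
        bad = set(self.sample_labels) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown sample labels: {sorted(bad)}")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def case_matrix(self) -> pd.DataFrame:
        mask = [lab == "case" for lab in self.sample_labels]
        return self.values.loc[:, mask]

    def control_matrix(self) -> pd.DataFrame:
        mask = [lab == "control" for lab in self.sample_labels]
        return self.values.loc[:, mask]

    # -- serialisation -------------------------------------------------------

    def to_tsv(self, matrix_path: str | Path, labels_path: str | Path) -> None:
        """Write the matrix (first column ``gene``) and a companion labels TSV."""
        out = self.values.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(matrix_path, sep="\t", index=False, float_format="%.6g")
        labels = pd.DataFrame(
            {"sample": list(self.values.columns), "class": list(self.sample_labels)}
        )
        labels.to_csv(labels_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, labels_path: str | Path) -> "ExpressionDataset":
        mat = pd.read_csv(matrix_path, sep="\t", dtype={"gene": str})
        mat = mat.set_index("gene")
        mat.index.name = None
        labels = pd.read_csv(labels_path, sep="\t", dtype=str)
        order = {s: c for s, c in zip(labels["sample"], labels["class"])}
        return cls(values=mat, sample_labels=tuple(order[c] for c in mat.columns))


def simulate_expression(
    net: InteractionNetwork,
    split: GoldStandardSplit,
    config: SimulationConfig,
) -> ExpressionDataset:
    """Draw a full expression matrix for the network under a planted split.

    Genes are ordered lexicographically; case samples come first
    (``case_001`` ...), controls last (``control_01`` ...). The draw is fully
    determined by ``config.seed``: a single vectorised normal draw against
    per-entry mean/scale arrays, so identical inputs give identical output.
    """
    if not split.matches_network(net):
        raise ValueError("split does not partition this network's node set")

    genes = net.sorted_nodes()
    n_genes = len(genes)
    n_samples = config.n_cases + config.n_controls
    fg_mask = np.array([g in split.fg_nodes for g in genes])
    case_mask = np.array([True] * config.n_cases + [False] * config.n_controls)

    mean = np.zeros((n_genes, n_samples))
    var = np.ones((n_genes, n_samples))
    if config.model == "VM":
        var[:] = config.v
        mean[np.ix_(fg_mask, case_mask)] = config.mu_fg
        mean[np.ix_(fg_mask, ~case_mask)] = config.mu_fgc
    else:
        mean[:] = config.mu
        var[:] = config.v_bg
        var[np.ix_(fg_mask, case_mask)] = config.v_fg

    rng = np.random.default_rng(config.seed)
    values = rng.normal(loc=mean, scale=np.sqrt(var))

    case_width = len(str(config.n_cases))
    ctrl_width = len(str(config.n_controls))
    columns = [f"case_{i + 1:0{case_width}d}" for i in range(config.n_cases)] + [
        f"control_{i + 1:0{ctrl_width}d}" for i in range(config.n_controls)
    ]
    frame = pd.DataFrame(values, index=genes, columns=columns)
    labels = tuple(["case"] * config.n_cases + ["control"] * config.n_controls)
    return ExpressionDataset(values=frame, sample_labels=labels)


def differential_stats(dataset: ExpressionDataset) -> pd.DataFrame:
    """Per-gene Welch two-sample t-test of case vs. control columns.

    Returns a DataFrame indexed by gene with columns ``t``, ``p``, ``p_adj``
    (Benjamini-Hochberg), ``mean_case`` and ``mean_control``. The Welch test
    is used because the VV model deliberately breaks variance homogeneity.
    Degenerate genes with zero variance in both classes get ``p = 1`` when
    the class means are equal (no evidence either way) and ``p = 0``
    otherwise (the separation is perfect).
    """
    case = dataset.case_matrix().to_numpy()
    control = dataset.control_matrix().to_numpy()
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("need at least two samples per class for a t-test")

    import warnings

    with warnings.catch_warnings():
        # constant genes trigger a scipy precision warning; they are handled
        # explicitly below
        warnings.filterwarnings(
            "ignore", message="Precision loss occurred", category=RuntimeWarning
        )
        t, p = stats.ttest_ind(case, control, axis=1, equal_var=False)
    mean_case = case.mean(axis=1)
    mean_control = control.mean(axis=1)

    degenerate = np.isnan(t)
    if degenerate.any():
        equal = np.isclose(mean_case, mean_control)
        t_fix = np.where(equal, 0.0, np.where(mean_case > mean_control, np.inf, -np.inf))
        t = np.where(degenerate, t_fix, t)
        p = np.where(degenerate, np.where(equal, 1.0, 0.0), p)

    return pd.DataFrame(
        {
            "t": t,
            "p": p,
            "p_adj": stats.false_discovery_control(p, method="bh"),
            "mean_case": mean_case,
            "mean_control": mean_control,
        },
        index=list(dataset.gene_ids),
    )


def write_differential_stats(table: pd.DataFrame, path: str | Path) -> None:
    """Serialise a :func:`differential_stats` table as TSV (first column ``gene``)."""
    out = table.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
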