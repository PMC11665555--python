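"""Run configuration shared by every pipeline stage.

The defaults encode the analysis constants the pipeline is built around:
10,000 genome permutations for the master-regulator null, the dual
P < 0.05 selection rule (Fisher and permutation), DEG thresholds of
adjusted p < 0.05 and |log2FC| >= 1, a 10%-90% quantile window for the
survival cutpoint scan, and a top-30 metabolite heatmap.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when an AnalysisConfig violates one of its invariants."""


def _check_prob(name: str, value: float) -> None:
    if not (0.0 < value < 1.0):
        raise ConfigError(f"{name} must lie in (0, 1); got {value!r}")


@dataclass
class AnalysisConfig:
    """Tunable parameters for a full pipeline run.

    Parameters
    ----------
    seed
        Master seed; every stage derives its own substream from it.
    permutations
        Number of genome resamplings for the empirical MRA null (B).
    alpha_fisher, alpha_perm
        Dual selection thresholds for master regulators.
    deg_padj_cutoff, deg_lfc_cutoff
        Significance thresholds defining the DEG set from a DEG table.
    cutoff_grid_quantiles
        (low, high) quantile window restricting survival cutpoint candidates.
    n_cutoffs
        Number of quantile-spaced cutpoint candidates inside the window
        (odd values include the median); ``None`` scans every distinct
        observed expression value in the window.
    top_k_metabolites
        Number of top differentially enriched metabolites exported for
        the clustered heatmap.
    multiple_testing
        "bh" adds Benjamini-Hochberg adjusted columns to stage outputs;
        "none" disables them.  Selection rules never use them.
    fisher_alternative
        "greater" (over-representation, default) or "two-sided".
    combine_method
        Cross-omics p-value combination: "fisher" (default) or "stouffer".
    posthoc_method
        ANOVA post hoc: "tukey" (default) or "t_bh" (pairwise t with BH).
    log_transform
        Log2-transform metabolite abundances before ANOVA.
    cutpoint_rule
        "min_p" (default) or "max_abs_loghr" for choosing the optimal cutoff.
    """

    seed: int = 0
    permutations: int = 10_000
    alpha_fisher: float = 0.05
    alpha_perm: float = 0.05
    deg_padj_cutoff: float = 0.05
    deg_lfc_cutoff: float = 1.0
    cutoff_grid_quantiles: tuple[float, float] = (0.10, 0.90)
    n_cutoffs: int | None = 41
    top_k_metabolites: int = 30
    multiple_testing: str = "bh"
    fisher_alternative: str = "greater"
    combine_method: str = "fisher"
    posthoc_method: str = "tukey"
    log_transform: bool = True
    cutpoint_rule: str = "min_p"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if int(self.permutations) < 1:
            raise ConfigError(
                f"permutations must be >= 1; got {self.permutations!r}"
            )
        for name in ("alpha_fisher", "alpha_perm", "deg_padj_cutoff"):
            _check_prob(name, float(getattr(self, name)))
        if self.deg_lfc_cutoff < 0:
            raise ConfigError("deg_lfc_cutoff must be non-negative")
        lo, hi = self.cutoff_grid_quantiles
        _check_prob("cutoff_grid_quantiles[0]", lo)
        _check_prob("cutoff_grid_quantiles[1]", hi)
        if not lo < hi:
            raise ConfigError(
                "cutoff_grid_quantiles must be strictly increasing; "
                f"got {self.cutoff_grid_quantiles!r}"
            )
        if self.n_cutoffs is not None and int(self.n_cutoffs) < 2:
            raise ConfigError("n_cutoffs must be >= 2 or None")
        if int(self.top_k_metabolites) < 0:
            raise ConfigError("top_k_metabolites must be >= 0")
        if self.multiple_testing not in ("none", "bh"):
            raise ConfigError("multiple_testing must be 'none' or 'bh'")
        if self.fisher_alternative not in ("greater", "two-sided"):
            raise ConfigError("fisher_alternative must be 'greater' or 'two-sided'")
        if self.combine_method not in ("fisher", "stouffer"):
            raise ConfigError("combine_method must be 'fisher' or 'stouffer'")
        if self.posthoc_method not in ("tukey", "t_bh"):
            raise ConfigError("posthoc_method must be 'tukey' or 't_bh'")
        if self.cutpoint_rule not in ("min_p", "max_abs_loghr"):
            raise ConfigError("cutpoint_rule must be 'min_p' or 'max_abs_loghr'")

    def replace(self, **changes: Any) -> "AnalysisConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["cutoff_grid_quantiles"] = list(self.cutoff_grid_quantiles)
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "AnalysisConfig":
        data = dict(data)
        if "cutoff_grid_quantiles" in data:
            data["cutoff_grid_quantiles"] = tuple(data["cutoff_grid_quantiles"])
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a flat mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
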