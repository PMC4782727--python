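"""Model/Results facade for the tip-dating analysis.

``TipDatingModel`` binds the data (character matrix, topology,
calibrations, priors); ``fit`` runs the MC3 sampler and returns a
``TipDatingResults`` carrying the posterior summary, diagnostics, and
the downstream biochronology conveniences (locality averaging, the TD2
re-run, branch-rate painting).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .biochron import locality_average, locality_estimates, rate_paint
from .matrix import CalibrationTable, CharacterMatrix
from .mcmc import ChainConfig, MCMCOutput, PosteriorSummary, run_mcmc, summarize
from .priors import PriorSet
from .trees import Tree

__all__ = ["TipDatingModel", "TipDatingResults"]


class TipDatingModel:
    """Joint model of tip ages, node ages, branch rates, and Mk parameters."""

    def __init__(self, matrix: CharacterMatrix | None, topology: Tree,
                 calibrations: CalibrationTable,
                 priors: PriorSet | None = None,
                 config: ChainConfig | None = None):
        if matrix is not None and not matrix.is_recoded:
            raise ValueError("recode the matrix before model construction")
        self.matrix = matrix
        self.topology = topology
        self.calibrations = calibrations
        self.priors = priors or PriorSet()
        self.config = config or ChainConfig()
        calibrations.validate_tips(topology.leaf_labels())

    @classmethod
    def from_files(cls, matrix_path, tree_path, calibrations_path,
                   **kwargs) -> "TipDatingModel":
        from .matrix import read_calibrations, read_nexus_matrix, recode_polymorphisms
        from .trees import read_tree
        matrix = recode_polymorphisms(read_nexus_matrix(matrix_path))
        return cls(matrix, read_tree(tree_path),
                   read_calibrations(calibrations_path), **kwargs)

    def fit(self, seed: int = 0, **config_overrides) -> "TipDatingResults":
        config = (replace(self.config, **config_overrides)
                  if config_overrides else self.config)
        output = run_mcmc(self.matrix, self.topology, self.calibrations,
                          self.priors, config, seed)
        return TipDatingResults(self, output, summarize(output))


class TipDatingResults:
    """Posterior summary of a fitted tip-dating model."""

    def __init__(self, model: TipDatingModel, output: MCMCOutput,
                 summary: PosteriorSummary):
        self.model = model
        self.output = output
        self._summary = summary

    @property
    def tip_ages(self) -> pd.DataFrame:
        """Per-tip posterior mean age and 95% HPD (Ma)."""
        return self._summary.tip_ages

    @property
    def parameters(self) -> pd.DataFrame:
        return self._summary.parameters

    @property
    def consensus(self) -> Tree:
        return self._summary.consensus

    @property
    def clade_pp(self) -> dict:
        return self._summary.clade_pp

    @property
    def asdsf(self) -> float:
        return self._summary.asdsf

    @property
    def posterior_summary(self) -> PosteriorSummary:
        return self._summary

    def locality_table(self, locality_map: dict[str, str],
                       fossil_only: bool = True):
        """Locality mean ages from per-tip posterior means."""
        means = {}
        for tip, row in self.tip_ages.iterrows():
            if fossil_only and row["mean"] <= 1e-9:
                continue
            means[tip] = float(row["mean"])
        return locality_estimates(means, locality_map)

    def td2_calibrations(self, locality_map: dict[str, str]) -> CalibrationTable:
        """Fixed calibrations for the second-stage run (locality means)."""
        means = {tip: float(row["mean"]) for tip, row in self.tip_ages.iterrows()
                 if float(row["mean"]) > 1e-9}
        return locality_average(means, locality_map)

    def refit_fixed(self, locality_map: dict[str, str], seed: int = 0,
                    **config_overrides) -> "TipDatingResults":
        """The TD2 stage: refit with tips fixed at locality means."""
        fixed = self.td2_calibrations(locality_map)
        for tip in self.model.calibrations.tips():
            if tip not in fixed:
                lo, hi = self.model.calibrations.bounds(tip)
                fixed.entries[tip] = {"kind": "fixed", "fixed_age": lo,
                                      "locality": self.model.calibrations.locality(tip)}
        model = TipDatingModel(self.model.matrix, self.model.topology, fixed,
                               self.model.priors, self.model.config)
        return model.fit(seed=seed, **config_overrides)

    def painted_rates(self) -> dict:
        """Absolute per-branch rates (changes per character per Ma)."""
        return rate_paint(self._summary)

    def summary(self) -> str:
        p = self.parameters
        lines = [f"Tip-dating fit: {self.output.config.mode}, "
                 f"{self.output.config.n_runs} runs x "
                 f"{self.output.config.n_chains} chains, "
                 f"{self.output.config.n_generations} generations"]
        if np.isfinite(self.asdsf):
            lines.append(f"ASDSF: {self.asdsf:.4f}")
        lines.append("")
        lines.append(p.round(4).to_string())
        lines.append("")
        lines.append("Tip ages (Ma):")
        lines.append(self.tip_ages.round(2).to_string())
        return "\n".join(lines)
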