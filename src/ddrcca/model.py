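"""Top-level modelling interface.

:class:`DDRCCA` bundles the whole analysis — preprocessing, per-sub-domain
dimension reduction, CCA and permutation testing — behind a model object
built from data; :meth:`DDRCCA.fit` returns a :class:`DDRCCAResults` that
carries the estimates (canonical correlations, loadings, per-domain
dimensions), their significance, a text ``summary()``, cross-validation via
``cross_validate()``, and plotting helpers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cca import CCAModel, LoadingSet, PermutationResult, run_cca_pipeline
from .config import PipelineConfig
from .data import DomainPartition, SubjectTable
from .ddr import ReducedData, run_ddr
from .preprocess import preprocess_pipeline
from .stability import StabilityReport, run_stability


class DDRCCA:
    """Domain-driven dimension reduction + CCA model.

    Parameters
    ----------
    sm, bm
        Subjects × variables tables for the two data blocks (e.g. subject
        measures and connectivity edges), same subjects in the same order.
    sm_partition, bm_partition
        Sub-domain dictionaries for the two blocks.
    confounds
        Optional confound table; both blocks are residualized on it.
    config
        :class:`~ddrcca.config.PipelineConfig`; defaults used when omitted.
    """

    def __init__(
        self,
        sm: SubjectTable,
        bm: SubjectTable,
        sm_partition: DomainPartition,
        bm_partition: DomainPartition,
        confounds: SubjectTable | None = None,
        config: PipelineConfig | None = None,
    ):
        self.sm_raw = sm
        self.bm_raw = bm
        self.sm_partition = sm_partition
        self.bm_partition = bm_partition
        self.confounds = confounds
        self.config = config or PipelineConfig()

    @classmethod
    def from_dataframes(
        cls,
        sm: pd.DataFrame,
        bm: pd.DataFrame,
        sm_domains: dict[str, str],
        bm_domains: dict[str, str],
        confounds: pd.DataFrame | None = None,
        config: PipelineConfig | None = None,
    ) -> "DDRCCA":
        return cls(
            SubjectTable.from_dataframe(sm),
            SubjectTable.from_dataframe(bm),
            DomainPartition(mapping=sm_domains),
            DomainPartition(mapping=bm_domains),
            None if confounds is None else SubjectTable.from_dataframe(confounds),
            config,
        )

    def _preprocess(self) -> tuple[SubjectTable, SubjectTable, dict]:
        cfg = self.config
        sm, sm_rep = preprocess_pipeline(
            self.sm_raw,
            confounds=self.confounds,
            benchmark=cfg.benchmark,
            manual_flips=cfg.manual_flips,
            square=cfg.confound_squares,
        )
        bm, bm_rep = preprocess_pipeline(self.bm_raw, confounds=self.confounds)
        return sm, bm, {"sm": sm_rep, "bm": bm_rep}

    def fit(self) -> "DDRCCAResults":
        """Run preprocessing, reduction, CCA and the permutation test."""
        cfg = self.config
        sm, bm, reports = self._preprocess()
        sm_reduced = run_ddr(
            sm, self.sm_partition.restrict(sm.variable_names),
            n_folds=cfg.n_folds, n_repeats=cfg.n_repeats,
            rng_seed=cfg.seed, center_folds=cfg.center_folds,
        )
        bm_reduced = run_ddr(
            bm, self.bm_partition.restrict(bm.variable_names),
            n_folds=cfg.n_folds, n_repeats=cfg.n_repeats,
            rng_seed=(cfg.seed + 1) % 2**31, center_folds=cfg.center_folds,
        )
        blocks = None
        if cfg.block_permutation and sm.family_ids is not None:
            blocks = np.asarray(sm.family_ids)
        model, loadings, perm = run_cca_pipeline(
            sm_reduced,
            bm_reduced,
            bm_target_dim=cfg.bm_target_dim,
            n_perm=cfg.n_perm,
            alpha=cfg.alpha,
            rng_seed=(cfg.seed + 2) % 2**31,
            sm_observed=sm,
            bm_observed=bm,
            blocks=blocks,
            scheme="within" if blocks is not None else "exchange",
        )
        return DDRCCAResults(
            model=self,
            sm_processed=sm,
            bm_processed=bm,
            preprocess_reports=reports,
            sm_reduced=sm_reduced,
            bm_reduced=bm_reduced,
            cca=model,
            loadings=loadings,
            permutation=perm,
        )


@dataclass
class DDRCCAResults:
    """Fitted pipeline results."""

    model: DDRCCA
    sm_processed: SubjectTable
    bm_processed: SubjectTable
    preprocess_reports: dict
    sm_reduced: ReducedData
    bm_reduced: ReducedData
    cca: CCAModel
    loadings: dict[str, LoadingSet]
    permutation: PermutationResult

    @property
    def canonical_correlations(self) -> np.ndarray:
        return self.cca.correlations

    @property
    def pvalues(self) -> np.ndarray:
        return self.permutation.p_values

    @property
    def n_significant(self) -> int:
        return self.permutation.n_significant

    def domain_summary(self) -> pd.DataFrame:
        rows = []
        for label, reduced in (("sm", self.sm_reduced), ("bm", self.bm_reduced)):
            for red in reduced.source:
                rows.append(
                    {
                        "block": label,
                        "subdomain": red.subdomain_label,
                        "n_vars": red.n_vars,
                        "chosen_k": red.chosen_k,
                        "variance_explained_pct": red.variance_explained_pct,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self, max_components: int = 10) -> str:
        """Human-readable summary of dimensions, correlations and tests."""
        cfg = self.model.config
        m = min(max_components, self.cca.m)
        lines = [
            "Domain-driven dimension reduction + CCA",
            "=" * 55,
            f"subjects: {self.sm_processed.n_subjects}",
            f"block 1: {self.sm_processed.n_variables} variables -> "
            f"{self.sm_reduced.components.shape[1]} factors "
            f"({len(self.sm_reduced.source)} sub-domains)",
            f"block 2: {self.bm_processed.n_variables} variables -> "
            f"{self.bm_reduced.components.shape[1]} factors "
            f"({len(self.bm_reduced.source)} sub-domains)",
            f"permutations: {self.permutation.n_perm}, "
            f"alpha: {self.permutation.alpha:g}, seed: {cfg.seed}",
            f"significant canonical pairs: {self.n_significant}",
            "-" * 55,
            f"{'pair':>4} {'corr':>8} {'p':>10} {'VE1 %':>8} {'VE2 %':>8}",
        ]
        ve1 = self.loadings["sm"].ve_pct
        ve2 = self.loadings["bm"].ve_pct
        for i in range(m):
            star = " *" if i < self.n_significant else ""
            lines.append(
                f"{i + 1:>4} {self.canonical_correlations[i]:>8.3f} "
                f"{self.pvalues[i]:>10.4f} {ve1[i]:>8.3f} {ve2[i]:>8.3f}{star}"
            )
        lines.append("-" * 55)
        lines.append("* significant (sequential max-statistic permutation test)")
        return "\n".join(lines)

    def cross_validate(
        self,
        n_folds: int | None = None,
        n_perm: int | None = None,
        n_repeats: int | None = None,
        rng_seed: int | None = None,
    ) -> StabilityReport:
        """Family-respecting k-fold stability analysis of the pipeline."""
        cfg = self.model.config
        return run_stability(
            self.sm_processed,
            self.bm_processed,
            self.model.sm_partition.restrict(self.sm_processed.variable_names),
            self.model.bm_partition.restrict(self.bm_processed.variable_names),
            n_folds=n_folds or cfg.n_folds,
            n_repeats=n_repeats or max(1, cfg.n_repeats // 5),
            bm_target_dim=cfg.bm_target_dim,
            n_perm=n_perm or cfg.n_perm,
            alpha=cfg.alpha,
            top_t=cfg.top_t,
            min_occurrence=cfg.min_occurrence,
            rng_seed=cfg.seed if rng_seed is None else rng_seed,
            center_folds=cfg.center_folds,
        )

    def plot_press(self, block: str = "sm", ax=None):
        """PRESS and naive error curves per sub-domain of one block."""
        import matplotlib.pyplot as plt

        reduced = self.sm_reduced if block == "sm" else self.bm_reduced
        curves = [r for r in reduced.source if r.press_curve is not None]
        if ax is None:
            _, ax = plt.subplots()
        for red in curves:
            c = red.press_curve
            (line,) = ax.plot(c.k_values, c.press, label=red.subdomain_label)
            ax.plot(c.k_values, c.naive_press, ls=":", color=line.get_color())
            ax.plot([red.chosen_k], [c.press[red.chosen_k - 1]], "o",
                    color=line.get_color())
        ax.set_xlabel("retained dimension k")
        ax.set_ylabel("PRESS (solid), naive error (dotted)")
        ax.legend(fontsize="x-small")
        return ax

    def plot_loadings(self, component: int = 1, block: str = "sm",
                      level: str = "observed", top: int = 20, ax=None):
        """Bar plot of the top canonical loadings for one component."""
        import matplotlib.pyplot as plt

        ls = self.loadings[block]
        mat = ls.observed_loadings if level == "observed" else ls.factor_loadings
        names = ls.observed_names if level == "observed" else ls.factor_names
        col = mat[:, component - 1]
        order = np.argsort(-np.abs(col))[:top]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.3 * len(order) + 1))
        ax.barh([names[i] for i in order][::-1], col[order][::-1])
        ax.set_xlabel(f"canonical loading (component {component}, {block})")
        return ax
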