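"""Model/Results facade over the two-stage threshold-derivation procedure.

``MovementCategoryModel`` is built from a cohort of cleaned velocity traces
(or a directory of trace files); ``fit()`` runs pooling, elbow selection
and per-match spectral clustering, returning a ``MovementCategoryResults``
that carries the cohort thresholds, their across-match dispersion, the
elbow curve and a printable summary in the style of published
movement-category tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cleaning import CohortCleaningSummary, load_cohort
from .config import PipelineConfig, default_config
from .spectral import ZoneThresholds, derive_cohort_thresholds
from .trace import VelocityTrace
from .zones import ZoneScheme, cohort_profiles

__all__ = ["MovementCategoryModel", "MovementCategoryResults"]


class MovementCategoryModel:
    """Unsupervised movement-category model for one cohort.

    Parameters
    ----------
    traces : list of VelocityTrace
        Cleaned traces of a single cohort.
    config : PipelineConfig, optional
        Grid, beta, k-selection range and seeds; package defaults if omitted.
    cohort : str, optional
        Cohort label; defaults to the traces' sex field.
    """

    def __init__(
        self,
        traces: list[VelocityTrace],
        config: PipelineConfig | None = None,
        cohort: str | None = None,
    ):
        if not traces:
            raise ValueError("need at least one trace")
        self.traces = traces
        self.config = config or default_config()
        self.cohort = cohort or traces[0].sex
        self.cleaning_summary: CohortCleaningSummary | None = None

    @classmethod
    def from_directory(
        cls,
        trace_dir: str | Path,
        cohort: str,
        config: PipelineConfig | None = None,
    ) -> "MovementCategoryModel":
        """Load, clean and filter every ``*.csv`` trace in a directory."""
        config = config or default_config()
        paths = sorted(Path(trace_dir).glob("*.csv"))
        groups, summary = load_cohort(
            paths, config.spike_cutoff, config.max_removed_fraction
        )
        if cohort not in groups:
            raise ValueError(f"no retained traces for cohort {cohort!r} in {trace_dir}")
        model = cls(groups[cohort], config=config, cohort=cohort)
        model.cleaning_summary = summary
        return model

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        config: PipelineConfig | None = None,
        cohort: str | None = None,
        sample_hz: float = 10.0,
    ) -> "MovementCategoryModel":
        """Build from a long table with columns match_id, time_s, velocity_mps
        and optional player_id / sex columns."""
        traces = []
        for mid, g in df.groupby("match_id", sort=True):
            traces.append(
                VelocityTrace(
                    player_id=str(g["player_id"].iloc[0]) if "player_id" in g else str(mid),
                    match_id=str(mid),
                    sex=str(g["sex"].iloc[0]) if "sex" in g else (cohort or "other"),
                    sample_hz=sample_hz,
                    times=g["time_s"].to_numpy(float),
                    velocities=g["velocity_mps"].to_numpy(float),
                )
            )
        return cls(traces, config=config, cohort=cohort)

    def fit(self, k: int | str | None = None, seed: int | None = None) -> "MovementCategoryResults":
        """Run the two-stage procedure and return the fitted results.

        ``k`` defaults to the config's k_mode ('auto' selects it by the
        elbow rule); ``seed`` overrides the config seed for k-means.
        """
        cfg = self.config
        thresholds = derive_cohort_thresholds(
            self.traces,
            k=k if k is not None else cfg.k_mode,
            grid=cfg.grid,
            beta=cfg.beta,
            k_range=cfg.k_range,
            seed=seed if seed is not None else cfg.seed,
            cohort=self.cohort,
        )
        return MovementCategoryResults(self, thresholds)


class MovementCategoryResults:
    """Fitted movement categories: thresholds, dispersion, diagnostics."""

    def __init__(self, model: MovementCategoryModel, thresholds: ZoneThresholds):
        self.model = model
        self.thresholds = thresholds

    # -- estimates -------------------------------------------------------
    @property
    def k(self) -> int:
        return self.thresholds.k

    @property
    def boundaries(self) -> np.ndarray:
        """Cohort-mean boundary velocities (m/s), reporting precision."""
        return self.thresholds.boundaries_rounded

    @property
    def boundaries_se(self) -> np.ndarray:
        """Standard error of each boundary across the cohort's matches."""
        table = self.thresholds.per_match_boundaries
        if len(table) < 2:
            return np.full(self.k - 1, np.nan)
        return table.std(axis=0, ddof=1) / np.sqrt(len(table))

    @property
    def elbow_curve(self):
        return self.thresholds.elbow

    def zone_scheme(self, zone_names: tuple[str, ...] | None = None) -> ZoneScheme:
        """Derived zones as a scheme usable for load quantification."""
        names = zone_names or tuple(
            ["low", "moderate", "high", "very_high"][: self.k]
            if self.k <= 4
            else [f"zone{i + 1}" for i in range(self.k)]
        )
        return ZoneScheme(f"derived-{self.thresholds.cohort}", tuple(self.boundaries), names)

    def profile(self, traces: list[VelocityTrace] | None = None):
        """Per-match activity profiles under the derived zones."""
        return cohort_profiles(traces or self.model.traces, self.zone_scheme())

    # -- presentation ----------------------------------------------------
    def summary(self) -> str:
        t = self.thresholds
        lines = [
            "Movement-category velocity thresholds",
            "=" * 45,
            f"cohort:        {t.cohort}",
            f"matches used:  {len(t.match_ids)}",
            f"k (categories):{t.k:>3}"
            + ("  (elbow-selected)" if t.elbow is not None else "  (fixed)"),
            f"config hash:   {self.model.config.config_hash}",
            "-" * 45,
        ]
        se = self.boundaries_se
        edges = [0.0, *self.boundaries]
        for z in range(t.k):
            lo = edges[z]
            hi = f"{self.boundaries[z]:.2f}" if z < t.k - 1 else "   —"
            se_txt = f"  (boundary SE {se[z]:.3f})" if z < t.k - 1 and np.isfinite(se[z]) else ""
            lines.append(f"Zone {z + 1} (m/s): {lo:5.2f} – {hi}{se_txt}")
        if t.elbow is not None:
            lines.append("-" * 45)
            wcss = ", ".join(f"{w:.1f}" for w in t.elbow.wcss_values)
            lines.append(f"elbow: k in [{t.elbow.k_values[0]}, {t.elbow.k_values[-1]}], "
                         f"WCSS = [{wcss}]")
        return "\n".join(lines)

    def plot_elbow(self, ax=None):
        """WCSS-vs-k curve with the selected elbow marked."""
        import matplotlib.pyplot as plt

        if self.elbow_curve is None:
            raise ValueError("model was fitted at fixed k; no elbow curve")
        if ax is None:
            _, ax = plt.subplots()
        e = self.elbow_curve
        ax.plot(e.k_values, e.wcss_values, "o-")
        ax.axvline(e.k_star, color="crimson", ls="--", label=f"k* = {e.k_star}")
        ax.set_xlabel("number of categories k")
        ax.set_ylabel("within-cluster sum of squares (m$^2$ s$^{-2}$)")
        ax.legend()
        return ax

    def plot_zones(self, ax=None):
        """Pooled velocity occupancy with threshold lines overlaid."""
        import matplotlib.pyplot as plt

        from .traversal import pool_traversals, traversal_matrix

        if ax is None:
            _, ax = plt.subplots()
        grid = self.model.config.grid
        pooled = pool_traversals([traversal_matrix(t, grid) for t in self.model.traces])
        ax.bar(grid.centers, pooled.occupancy, width=grid.width, color="0.7")
        for b in self.boundaries:
            ax.axvline(b, color="crimson", ls="--")
        ax.set_xlabel("velocity (m/s)")
        ax.set_ylabel("occupancy (traversal row sums)")
        return ax
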