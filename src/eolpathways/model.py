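"""Care-pathway model and results objects.

`CarePathwayModel` bundles the three data tables of a decedent cohort —
the cohort characteristics, the daily care-state sequences and the costed
claims — and `fit()` runs the sequence analysis: optional random sampling
of patients, pairwise optimal-matching dissimilarities, Ward hierarchical
classification, tree cutting and cluster naming.  The returned
`CarePathwayResults` carries the typology and exposes the derived data
products: chronograms, index-plot orders, per-cluster characteristic and
cost profiles, expenditure tables, and the pathway-membership logistic
association.

Example
-------
>>> from eolpathways import CarePathwayModel
>>> model, truth = CarePathwayModel.simulate()
>>> res = model.fit(k=3, seed=0)
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clustering, costing, descriptives
from .distance import (
    CostScheme,
    DissimilarityMatrix,
    dissimilarity_matrix,
    sample_patients,
)
from .simulate import (
    ArchetypeConfig,
    CohortConfig,
    CostConfig,
    generate_claims,
    generate_cohort,
    generate_pathways,
)
from .states import SequenceSet


class CarePathwayModel:
    """End-of-life care-pathway sequence analysis for one decedent cohort.

    Parameters
    ----------
    sequences : SequenceSet
        Daily care-state sequences, one per patient.
    cohort : DataFrame, optional
        Patient characteristics (required for descriptive profiles and the
        association model).
    claims : DataFrame, optional
        Costed service claims (required for the expenditure analytics).
    cost_scheme : CostScheme, optional
        Edit costs for optimal matching; defaults to indel 1 /
        substitution 2 (the LCS metric).
    ward_variant : {"squared", "raw"}
        Ward linkage convention, see :func:`eolpathways.ward_linkage`.
    """

    def __init__(
        self,
        sequences: SequenceSet,
        cohort: pd.DataFrame | None = None,
        claims: pd.DataFrame | None = None,
        cost_scheme: CostScheme | None = None,
        ward_variant: str = "squared",
    ) -> None:
        if len(sequences) == 0:
            raise ValueError("at least one sequence is required")
        self.sequences = sequences
        self.cohort = None
        if cohort is not None:
            self.cohort = cohort.set_index("patient_id", drop=False) \
                if "patient_id" in cohort.columns else cohort
            missing = set(sequences.ids) - set(self.cohort.index)
            if missing:
                raise ValueError(f"sequences without cohort rows: {sorted(missing)[:5]}")
        self.claims = None
        if claims is not None:
            self.claims = costing.validate_claims(
                claims, None if self.cohort is None else list(self.cohort.index)
            )
        self.cost_scheme = cost_scheme or CostScheme()
        if ward_variant not in ("squared", "raw"):
            raise ValueError("ward_variant must be 'squared' or 'raw'")
        self.ward_variant = ward_variant

    # ------------------------------------------------------------------
    @classmethod
    def from_frames(
        cls,
        sequences: pd.DataFrame,
        cohort: pd.DataFrame | None = None,
        claims: pd.DataFrame | None = None,
        **kwargs,
    ) -> "CarePathwayModel":
        """Build the model from serialized tables (see the io module)."""
        return cls(SequenceSet.from_frame(sequences), cohort, claims, **kwargs)

    @classmethod
    def simulate(
        cls,
        cohort_config: CohortConfig | None = None,
        archetype_config: ArchetypeConfig | None = None,
        cost_config: CostConfig | None = None,
        **kwargs,
    ) -> tuple["CarePathwayModel", pd.Series]:
        """Generate a synthetic cohort and return (model, ground truth).

        The ground-truth archetype labels are returned *beside* the model,
        never stored on it: the analysis stages cannot read them.
        """
        cohort_config = cohort_config or CohortConfig()
        archetype_config = archetype_config or ArchetypeConfig()
        cost_config = cost_config or CostConfig()
        cohort = generate_cohort(cohort_config)
        sequences, labels = generate_pathways(cohort, archetype_config)
        claims = generate_claims(cohort, sequences, cost_config)
        truth = pd.Series(labels, index=list(cohort["patient_id"]), name="archetype")
        return cls(sequences, cohort, claims, **kwargs), truth

    # ------------------------------------------------------------------
    def fit(
        self,
        k: int | None = None,
        k_min: int = 2,
        k_max: int = 8,
        k_default: int = 3,
        sample_size: int | None = None,
        seed: int = 0,
        auto_name: bool = True,
    ) -> "CarePathwayResults":
        """Run the sequence analysis and return the fitted typology.

        Parameters
        ----------
        k : int, optional
            Number of pathway clusters; selected at the dendrogram elbow
            within [k_min, k_max] when omitted.
        sample_size : int, optional
            Random sample of patients entering the pairwise comparison
            (the reference analysis uses 10,000); all patients if omitted.
        seed : int
            Seed for the patient sampling.
        auto_name : bool
            Attach canonical pathway names derived from chronogram shape.
        """
        ids = list(self.sequences.ids)
        if sample_size is not None and sample_size < len(ids):
            ids = sample_patients(ids, sample_size, seed)
        seqs = self.sequences.subset(ids)
        D = dissimilarity_matrix(seqs, self.cost_scheme)
        tree = clustering.ward_linkage(D, variant=self.ward_variant)
        if k is None:
            k = clustering.select_k(tree, k_min, min(k_max, len(ids) - 1),
                                    default=k_default)
        typology = clustering.cut_tree(tree, k)
        if auto_name and k >= 1:
            chrono = clustering.chronogram(seqs, typology)
            typology.names = clustering.name_clusters(chrono)
        return CarePathwayResults(self, seqs, D, tree, typology)


@dataclass
class CarePathwayResults:
    """Fitted pathway typology and its derived summaries."""

    model: CarePathwayModel
    sample: SequenceSet
    dissimilarity: DissimilarityMatrix
    tree: "clustering.LinkageTree"
    typology: "clustering.ClusterTypology"
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def k(self) -> int:
        return self.typology.k

    @property
    def labels(self) -> pd.Series:
        return self.typology.labels

    # -- sequence data products ----------------------------------------
    def chronograms(self) -> "clustering.Chronogram":
        if "chronogram" not in self._cache:
            self._cache["chronogram"] = clustering.chronogram(self.sample, self.typology)
        return self._cache["chronogram"]

    def index_plot_order(self) -> dict:
        return clustering.index_plot_order(self.sample, self.typology)

    def place_of_death(self) -> pd.Series:
        return descriptives.place_of_death_summary(self.sample)

    # -- cohort summaries ----------------------------------------------
    def _need(self, what: str):
        value = getattr(self.model, what)
        if value is None:
            raise ValueError(f"this analysis requires the {what} table")
        return value

    def cluster_profile(self) -> pd.DataFrame:
        return clustering.cluster_profile(self.typology, self._need("cohort"))

    def characteristics(self) -> pd.DataFrame:
        return descriptives.characteristics_table(self._need("cohort"))

    def palliative(self) -> pd.DataFrame:
        return descriptives.palliative_summary(self._need("cohort"))

    def association(
        self, reference_cluster: int | None = None,
        features: pd.DataFrame | None = None,
    ) -> pd.DataFrame:
        """Odds ratios for membership in a pathway cluster (default: the
        highest-numbered, typically 'early and repeated hospitalizations')."""
        cohort = self._need("cohort")
        if reference_cluster is None:
            reference_cluster = self.k
        if features is None:
            features = pd.DataFrame(index=self.labels.index)
            sub = cohort.loc[self.labels.index]
            features["age_at_death"] = sub["age_at_death"]
            features["female"] = (sub["sex"] == "female").astype(float)
            features["charlson_score"] = sub["charlson_score"]
        return descriptives.pathway_association(features, self.labels,
                                                reference_cluster)

    # -- expenditure analytics -----------------------------------------
    def patient_totals(self, window_days: int = 365) -> pd.Series:
        claims = self._need("claims")
        cohort_ids = (list(self.model.cohort.index) if self.model.cohort is not None
                      else list(self.model.sequences.ids))
        return costing.patient_totals(claims, cohort_ids, window_days)

    def cost_table(self, window_days: int = 365) -> costing.CostSummaryTable:
        claims = self._need("claims")
        cohort_ids = (list(self.model.cohort.index) if self.model.cohort is not None
                      else list(self.model.sequences.ids))
        return costing.service_cost_table(claims, cohort_ids, window_days)

    def window_share(self, short_window: int = 90) -> float:
        return costing.window_share(self._need("claims"), None, short_window)

    def top_decile(self) -> costing.DecileSummary:
        return costing.top_decile_summary(self.patient_totals())

    def cluster_costs(self, window_days: int = 365) -> pd.DataFrame:
        totals = self.patient_totals(window_days).loc[self.labels.index]
        return costing.cluster_cost_summary(self.labels, totals)

    def cluster_cost_shares(self) -> pd.Series:
        table = self.cluster_costs()
        shares = costing.cluster_cost_share(table["n"].to_numpy(),
                                            table["mean"].to_numpy())
        return pd.Series(shares, index=table.index, name="cost_share")

    # -- rendering ------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary of the fitted typology."""
        lines = []
        n = len(self.sample)
        lines.append("            Care Pathway Typology")
        lines.append("=" * 74)
        lines.append(f"No. sequences: {n:<8d} clusters (k): {self.k:<4d} "
                     f"ward variant: {self.model.ward_variant}")
        lines.append(f"OM costs: indel={self.model.cost_scheme.indel:g}, "
                     f"substitution={self.model.cost_scheme.substitution.max():g}")
        lines.append("-" * 74)
        sizes = self.typology.sizes()
        have_costs = self.model.claims is not None
        costs = self.cluster_costs() if have_costs else None
        header = f"{'cluster':>7} {'n':>6} {'%':>6}"
        if have_costs:
            header += f" {'mean cost':>12} {'median':>10}"
        header += "  name"
        lines.append(header)
        for c in sizes.index:
            row = f"{c:>7d} {sizes[c]:>6d} {100 * sizes[c] / n:>6.1f}"
            if have_costs:
                row += (f" {costs.loc[c, 'mean']:>12,.0f}"
                        f" {costs.loc[c, 'median']:>10,.0f}")
            row += f"  {self.typology.names.get(c, '')}"
            lines.append(row)
        lines.append("=" * 74)
        return "\n".join(lines)

    def plot_chronogram(self, cluster: int | None = None, ax=None):
        """Stacked-area state distribution plot for one or all clusters."""
        import matplotlib.pyplot as plt

        from .states import STATE_CHARS, CareState

        chrono = self.chronograms()
        clusters = [cluster] if cluster is not None else sorted(chrono.frequencies)
        if ax is None:
            fig, axes = plt.subplots(len(clusters), 1, squeeze=False,
                                     figsize=(8, 2.2 * len(clusters)))
            axes = axes.ravel()
        else:
            axes = [ax]
        days = np.arange(-365, 0) + 1
        for axis, c in zip(axes, clusters):
            f = chrono.frequencies[c]
            axis.stackplot(days, f.T, labels=[s.name for s in CareState])
            axis.set_ylim(0, 1)
            axis.set_ylabel(f"cluster {c}")
        axes[-1].set_xlabel("days before death")
        axes[0].legend(loc="upper left", fontsize="x-small", ncol=5)
        return axes[0].figure

    def plot_index(self, ax=None):
        """Sequence index plot: one colored bar of daily states per patient."""
        import matplotlib.pyplot as plt

        order = self.index_plot_order()
        ids = [p for c in sorted(order) for p in order[c]]
        mat = self.sample.subset(ids).data
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        ax.imshow(mat, aspect="auto", interpolation="nearest", cmap="viridis")
        ax.set_xlabel("day of the last year (death at right)")
        ax.set_ylabel("patients (grouped by cluster)")
        return ax.figure
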