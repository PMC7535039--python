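"""Paired habitat statistics: normality-branched tests, Bonferroni
selection, correlation of paired differences, and PCA of region vectors.

The workflow mirrors the classic paired-cohort design: for each of the 47
features, form the per-subject difference d = value(recurrent) −
value(non-recurrent); Shapiro-Wilk decides between a paired t-test and a
Wilcoxon signed-rank test; Bonferroni (alpha/m) controls the family-wise
error over the m features; Pearson correlations and a PCA of the pooled
region vectors summarize the significant features.

The stage is exposed both as plain functions and as a model object:

>>> model = HabitatComparison(rec_rows, nonrec_rows)
>>> res = model.fit(alpha=0.05)
>>> print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .features.names import FEATURE_NAMES
from .io import FeatureVector

#: Shapiro-Wilk level below which the t-test's normality assumption is rejected.
SHAPIRO_ALPHA = 0.05

#: Fallback size of the feature set carried into correlation/PCA when no
#: feature survives Bonferroni.
TOP_K_FALLBACK = 7


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test level alpha/m; selection always uses the unrounded value
    (display layers may round, e.g. 0.05/47 prints as 0.001)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


@dataclass
class TestResult:
    feature: str
    test_used: str            # "paired_t" | "wilcoxon_signed_rank" | "degenerate"
    shapiro_p: float
    mean_diff: float
    sd_diff: float
    p_value: float
    significant: bool
    degenerate: bool = False


@dataclass
class PairedStudyTable:
    """Per-subject recurrent-minus-nonrecurrent differences, one column per feature."""

    differences: pd.DataFrame   # index: subject_id, columns: features
    subject_ids: list[str]

    @property
    def n(self) -> int:
        return len(self.subject_ids)


@dataclass
class PcaResult:
    loadings: pd.DataFrame              # features x components
    scores: pd.DataFrame                # region rows x components, with 'region' column
    explained_variance_fraction: np.ndarray
    feature_means: np.ndarray
    feature_sds: np.ndarray


def paired_differences(
    rec: list[FeatureVector], nonrec: list[FeatureVector]
) -> PairedStudyTable:
    """Recurrent-minus-nonrecurrent difference for every feature and subject."""
    if len(rec) != len(nonrec):
        raise ValueError("paired lists differ in length")
    ids_rec = [r.subject_id for r in rec]
    ids_non = [r.subject_id for r in nonrec]
    if ids_rec != ids_non:
        raise ValueError(f"subject ids do not match: {ids_rec} vs {ids_non}")
    rows = []
    for r, nr in zip(rec, nonrec):
        rows.append({f: r.values[f] - nr.values[f] for f in FEATURE_NAMES})
    df = pd.DataFrame(rows, index=ids_rec, columns=list(FEATURE_NAMES))
    return PairedStudyTable(differences=df, subject_ids=ids_rec)


def wilcoxon_signed_rank_p(d: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value under this package's convention:
    zero differences dropped, exact null distribution for n <= 25 without
    ties in |d|, otherwise normal approximation with continuity correction
    and average ranks for ties."""
    d = np.asarray(d, dtype=np.float64)
    dz = d[d != 0.0]
    if dz.size == 0:
        return float("nan")
    has_ties = np.unique(np.abs(dz)).size < dz.size
    if dz.size <= 25 and not has_ties:
        res = sps.wilcoxon(dz, zero_method="wilcox", method="exact")
    else:
        res = sps.wilcoxon(dz, zero_method="wilcox", correction=True, method="approx")
    return float(res.pvalue)


def test_feature(d: np.ndarray, alpha: float, m: int, feature: str = "") -> TestResult:
    """Normality-branched paired test of one difference column.

    Shapiro-Wilk at 0.05 decides the branch: t-test when normality is not
    rejected, Wilcoxon signed-rank otherwise (zeros dropped; exact null
    distribution for n <= 25 without ties, normal approximation with
    continuity correction otherwise).  Significance is judged against the
    unrounded Bonferroni level alpha/m.
    """
    d = np.asarray(d, dtype=np.float64)
    if d.size < 3:
        raise ValueError("need n >= 3 paired differences")
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    if sd_diff == 0.0:
        return TestResult(feature, "degenerate", float("nan"), mean_diff, 0.0,
                          float("nan"), False, degenerate=True)
    shapiro_p = float(sps.shapiro(d).pvalue)
    thresh = bonferroni_threshold(alpha, m)
    if shapiro_p < SHAPIRO_ALPHA:
        p = wilcoxon_signed_rank_p(d)
        if not np.isfinite(p):
            return TestResult(feature, "degenerate", shapiro_p, mean_diff, sd_diff,
                              float("nan"), False, degenerate=True)
        used = "wilcoxon_signed_rank"
    else:
        p = float(sps.ttest_1samp(d, 0.0).pvalue)
        used = "paired_t"
    return TestResult(feature, used, shapiro_p, mean_diff, sd_diff, p, p < thresh)


def correlation_matrix(
    table: PairedStudyTable, features: list[str], sig_level: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and p over the selected difference columns.

    Returns (r, p, mask) with mask marking p < sig_level (unadjusted, as
    in the usual correlation-heatmap display).
    """
    if len(features) < 2:
        raise ValueError("need >= 2 features")
    X = table.differences[features].to_numpy()
    if table.n < 3:
        raise ValueError("need n >= 3 subjects")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = [f for f, s in zip(features, sds) if s == 0]
        raise ValueError(f"zero-variance difference column(s): {bad}")
    k = len(features)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            rij, pij = sps.pearsonr(X[:, i], X[:, j])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    rdf = pd.DataFrame(r, index=features, columns=features)
    pdf = pd.DataFrame(p, index=features, columns=features)
    mask = pdf < sig_level
    return rdf, pdf, mask


def pca_regions(region_table: pd.DataFrame, features: list[str]) -> PcaResult:
    """PCA of the pooled recurrent + non-recurrent region vectors.

    ``region_table`` must carry a 'region' column ('recurrent' /
    'nonrecurrent') plus the feature columns.  Features are z-scored
    before the eigendecomposition (their scales differ by orders of
    magnitude); components are ordered by decreasing explained variance
    with the sign convention that each component's largest-magnitude
    loading is positive.
    """
    if len(features) < 2:
        raise ValueError("need >= 2 features")
    X = region_table[features].to_numpy(dtype=np.float64)
    if X.shape[0] < 3:
        raise ValueError("need >= 3 region rows")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [f for f, s in zip(features, sd) if s == 0]
        raise ValueError(f"constant feature column(s) after pooling: {bad}")
    Z = (X - mu) / sd
    pca = PCA()
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T  # features x components
    for c in range(loadings.shape[1]):
        lead = np.argmax(np.abs(loadings[:, c]))
        if loadings[lead, c] < 0:
            loadings[:, c] *= -1.0
            scores[:, c] *= -1.0
    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    scores_df = pd.DataFrame(scores, columns=comp_names, index=region_table.index)
    scores_df.insert(0, "region", region_table["region"].to_numpy())
    return PcaResult(
        loadings=pd.DataFrame(loadings, index=features, columns=comp_names),
        scores=scores_df,
        explained_variance_fraction=pca.explained_variance_ratio_,
        feature_means=mu,
        feature_sds=sd,
    )


class HabitatComparison:
    """Paired comparison of recurrent vs non-recurrent habitat features.

    Parameters
    ----------
    rec, nonrec : lists of FeatureVector
        Matched per-subject feature vectors of the two habitats.
    """

    def __init__(self, rec: list[FeatureVector], nonrec: list[FeatureVector]):
        self.rec = rec
        self.nonrec = nonrec
        self.table = paired_differences(rec, nonrec)

    @classmethod
    def from_feature_table(cls, df: pd.DataFrame) -> "HabitatComparison":
        """Build from a long feature table (columns: subject_id, roi_role, 47 features)."""
        rec_rows, nonrec_rows = [], []
        for sid, grp in df.groupby("subject_id", sort=True):
            by_role = {row["roi_role"]: row for _, row in grp.iterrows()}
            if "GTVr" not in by_role or "GTVnr" not in by_role:
                raise ValueError(f"subject {sid}: missing GTVr or GTVnr row")
            for role, sink in (("GTVr", rec_rows), ("GTVnr", nonrec_rows)):
                vals = {f: float(by_role[role][f]) for f in FEATURE_NAMES}
                und = {f: "read from table" for f, v in vals.items() if not np.isfinite(v)}
                sink.append(FeatureVector(vals, str(sid), role, und))
        return cls(rec_rows, nonrec_rows)

    def fit(self, alpha: float = 0.05) -> "HabitatComparisonResults":
        if self.table.n < 3:
            raise ValueError("need at least 3 subjects")
        diffs = self.table.differences
        tested = [f for f in FEATURE_NAMES if np.isfinite(diffs[f]).all()]
        dropped = [f for f in FEATURE_NAMES if f not in tested]
        if dropped:
            warnings.warn(f"features with undefined values excluded from testing: {dropped}")
        m = len(tested)
        results = [
            test_feature(diffs[f].to_numpy(), alpha, m, feature=f) for f in tested
        ]
        significant = [r.feature for r in results if r.significant]
        fallback = False
        selected = significant
        if len(selected) == 0:
            fallback = True
            ranked = sorted((r for r in results if not r.degenerate), key=lambda r: r.p_value)
            selected = [r.feature for r in ranked[:TOP_K_FALLBACK]]
            warnings.warn(
                "no feature survives Bonferroni; correlation/PCA run on the "
                f"top-{TOP_K_FALLBACK} features by p-value"
            )
        elif len(selected) == 1:
            # correlation/PCA need >= 2 columns; pad with the next-best feature
            ranked = sorted(
                (r for r in results if not r.degenerate and not r.significant),
                key=lambda r: r.p_value,
            )
            selected = selected + [ranked[0].feature] if ranked else selected

        corr = corr_p = corr_mask = None
        pca = None
        if len(selected) >= 2:
            corr, corr_p, corr_mask = correlation_matrix(self.table, selected)
            pca = pca_regions(self._region_table(selected), selected)
        return HabitatComparisonResults(
            model=self,
            alpha=alpha,
            m=m,
            tests=results,
            significant_features=significant,
            selected_features=selected,
            fallback_selection=fallback,
            corr=corr,
            corr_p=corr_p,
            corr_mask=corr_mask,
            pca=pca,
        )

    def _region_table(self, features: list[str]) -> pd.DataFrame:
        rows = []
        for fv in self.rec:
            rows.append({"region": "recurrent", **{f: fv.values[f] for f in features}})
        for fv in self.nonrec:
            rows.append({"region": "nonrecurrent", **{f: fv.values[f] for f in features}})
        idx = [fv.subject_id + "_rec" for fv in self.rec] + [
            fv.subject_id + "_nonrec" for fv in self.nonrec
        ]
        return pd.DataFrame(rows, index=idx)


@dataclass
class HabitatComparisonResults:
    """Estimates, tests and diagnostics of a fitted HabitatComparison."""

    model: HabitatComparison
    alpha: float
    m: int
    tests: list[TestResult]
    significant_features: list[str]
    selected_features: list[str]
    fallback_selection: bool
    corr: pd.DataFrame | None
    corr_p: pd.DataFrame | None
    corr_mask: pd.DataFrame | None
    pca: PcaResult | None
    _extra: dict = field(default_factory=dict)

    @property
    def threshold(self) -> float:
        return bonferroni_threshold(self.alpha, self.m)

    def tests_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "feature": r.feature,
                    "mean_diff": r.mean_diff,
                    "sd_diff": r.sd_diff,
                    "shapiro_p": r.shapiro_p,
                    "test_used": r.test_used,
                    "p_value": r.p_value,
                    "significant": r.significant,
                }
                for r in self.tests
            ]
        )

    def pc1_silhouette(self) -> float:
        """Silhouette of recurrent vs non-recurrent labels along PC1 alone."""
        if self.pca is None:
            raise ValueError("no PCA available")
        x = self.pca.scores[["PC1"]].to_numpy()
        labels = (self.pca.scores["region"] == "recurrent").to_numpy().astype(int)
        return float(silhouette_score(x, labels))

    def summary(self) -> str:
        df = self.tests_frame()
        n = self.model.table.n
        lines = [
            "Paired habitat feature comparison",
            "=" * 78,
            f"subjects: {n}    features tested: {self.m}    alpha: {self.alpha}",
            f"Bonferroni per-test level: {self.threshold:.3g} (displayed {round(self.threshold, 3):.3f})",
            f"significant features: {len(self.significant_features)}",
            "-" * 78,
            f"{'feature':<22}{'mean diff':>12}{'sd diff':>12}{'test':>20}{'p':>10}",
            "-" * 78,
        ]
        for _, row in df.sort_values("p_value").iterrows():
            star = " *" if row["significant"] else ""
            lines.append(
                f"{row['feature']:<22}{row['mean_diff']:>12.3g}{row['sd_diff']:>12.3g}"
                f"{row['test_used']:>20}{row['p_value']:>10.2g}{star}"
            )
        lines.append("-" * 78)
        if self.pca is not None:
            evf = self.pca.explained_variance_fraction
            lines.append(
                "PCA on selected features: "
                + ", ".join(f"PC{i + 1} {100 * v:.0f}%" for i, v in enumerate(evf[:3]))
            )
            lines.append(f"PC1 silhouette (recurrent vs non-recurrent): {self.pc1_silhouette():.3f}")
        if self.fallback_selection:
            lines.append("NOTE: no feature survived Bonferroni; selection fell back to top-k by p-value.")
        return "\n".join(lines)

    def save(self, outdir: str) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.tests_frame().to_csv(os.path.join(outdir, "tests.csv"), index=False)
        if self.corr is not None:
            self.corr.to_csv(os.path.join(outdir, "corr.csv"))
            self.corr_mask.to_csv(os.path.join(outdir, "corr_mask.csv"))
        if self.pca is not None:
            self.pca.scores.to_csv(os.path.join(outdir, "pca_scores.csv"))
            pd.DataFrame(
                {
                    "component": [f"PC{i + 1}" for i in range(self.pca.explained_variance_fraction.size)],
                    "explained_variance_fraction": self.pca.explained_variance_fraction,
                }
            ).to_csv(os.path.join(outdir, "pca_variance.csv"), index=False)
        with open(os.path.join(outdir, "report.txt"), "w") as fh:
            fh.write(self.summary() + "\n")


def run_statistics(
    rec: list[FeatureVector], nonrec: list[FeatureVector], alpha: float = 0.05
) -> HabitatComparisonResults:
    """One-call version of the full statistical stage."""
    return HabitatComparison(rec, nonrec).fit(alpha=alpha)
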