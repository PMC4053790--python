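"""Category-level divergence test: genome-wide Ka/Ks, per-category expected
non-synonymous proportion, binomial tail probabilities, and the
annotation-permutation null.

Model
-----
Let T be the ortholog universe with per-gene non-synonymous substitutions and
sites (a_i, A_i) and synonymous ones (s_i, S_i).  Genome-wide rates are
ratio-of-sums (equivalent to counting on the concatenated gene set):

    ka = Σ_{i∈T} a_i / Σ_{i∈T} A_i ,   ks = Σ_{i∈T} s_i / Σ_{i∈T} S_i .

For a GO category C, the expected proportion of non-synonymous substitutions
if C evolved at genome-average rates is

    P_A = ka·Σ_{i∈C} A_i / (ka·Σ_{i∈C} A_i + ks·Σ_{i∈C} S_i) ,

and the observed substitution total n_C = a_C + s_C is split binomially:
the upper tail P(j ≥ a_C), j ~ Binomial(n_C, P_A), flags rapidly evolving
categories, the lower tail P(j ≤ a_C) slowly evolving ones.  Both tails
include the observed value.  Tails are evaluated through the regularized
incomplete beta function, which coincides with the binomial sum at integer
counts and extends it continuously to the fractional counts that pathway
averaging produces.

Because category membership is not random — genes sharing a function share
selective constraints only partly — per-category tails are not corrected for
multiple testing; instead the number of categories below each threshold is
compared with its null distribution under random re-assignment of whole
per-gene annotation sets (term sizes preserved), giving an expected
false-positive count and a global permutation p-value per (direction,
threshold).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import betainc

from .annotation import GoAnnotation, GoCategory, build_categories, read_annotation
from .codon_counts import SubstitutionCounts, read_counts_table

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeRates",
    "CategoryResult",
    "PermutationSummary",
    "genome_rates",
    "expected_nonsyn_proportion",
    "tail_probability",
    "test_all_categories",
    "count_outliers",
    "permutation_null",
    "CategoryDivergenceModel",
    "CategoryDivergenceResults",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS: tuple[float, ...] = (0.05, 0.01, 0.001, 0.0001)


@dataclass(frozen=True)
class GenomeRates:
    """Genome-wide ka, ks as ratio-of-sums over the ortholog universe."""

    ka: float
    ks: float
    n_genes: int

    def __post_init__(self) -> None:
        if self.ka < 0 or self.ks < 0:
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class CategoryResult:
    """Per-category sums, rates, expected proportion and both tail probabilities."""

    term_id: str
    n_genes: int
    a_C: float
    s_C: float
    sum_A: float
    sum_S: float
    ka_C: float
    ks_C: float
    ka_ks_C: float
    P_A: float
    p_rapid: float
    p_slow: float


@dataclass(frozen=True)
class PermutationSummary:
    """Observed vs expected outlier counts at one (direction, threshold).

    ``expected_count`` is the mean outlier count over permuted annotations —
    the expected number of false positives among the observed outliers.
    ``global_p`` uses the add-one estimator (1 + #{count ≥ observed}) /
    (1 + n_permutations); ``plain_p`` is the raw proportion.
    """

    direction: str
    threshold: float
    observed_count: int
    expected_count: float
    sd_count: float
    global_p: float
    plain_p: float
    n_permutations: int
    seed: int | None


def genome_rates(counts: Iterable[SubstitutionCounts]) -> GenomeRates:
    """Ratio-of-sums ka and ks over all genes (counting on the concatenated set)."""
    counts = list(counts)
    if not counts:
        raise ValueError("no substitution counts supplied")
    sa = sum(c.a for c in counts)
    sA = sum(c.A for c in counts)
    ss = sum(c.s for c in counts)
    sS = sum(c.S for c in counts)
    if sA <= 0:
        raise ValueError("total non-synonymous sites is zero")
    if sS <= 0:
        raise ValueError("total synonymous sites is zero; ks undefined")
    return GenomeRates(ka=sa / sA, ks=ss / sS, n_genes=len(counts))


def expected_nonsyn_proportion(sum_A: float, sum_S: float, rates: GenomeRates) -> float:
    """P_A = ka·ΣA / (ka·ΣA + ks·ΣS) for a category with site sums (ΣA, ΣS)."""
    if sum_A <= 0 or sum_S <= 0:
        raise ValueError("category site sums must be positive")
    denom = rates.ka * sum_A + rates.ks * sum_S
    if denom <= 0:
        raise ValueError("ka·ΣA + ks·ΣS is zero; expected proportion undefined")
    return rates.ka * sum_A / denom


def _p_rapid_arr(a, s, p) -> np.ndarray:
    """P(j ≥ a), j ~ Binomial(a+s, p), continuous in (a, s) via I_p(a, s+1)."""
    a, s, p = np.broadcast_arrays(
        np.asarray(a, dtype=float), np.asarray(s, dtype=float), np.asarray(p, dtype=float)
    )
    out = np.ones(a.shape)
    pos = a > 0
    if np.any(pos):
        out[pos] = betainc(a[pos], s[pos] + 1.0, p[pos])
    return out


def _p_slow_arr(a, s, p) -> np.ndarray:
    """P(j ≤ a) = I_{1−p}(s, a+1), continuous in (a, s)."""
    a, s, p = np.broadcast_arrays(
        np.asarray(a, dtype=float), np.asarray(s, dtype=float), np.asarray(p, dtype=float)
    )
    out = np.ones(a.shape)
    pos = s > 0
    if np.any(pos):
        out[pos] = betainc(s[pos], a[pos] + 1.0, 1.0 - p[pos])
    return out


def tail_probability(a_C: float, s_C: float, P_A: float, direction: str) -> float:
    """Binomial tail probability for a category's substitution split.

    direction="rapid": P(j ≥ a_C); direction="slow": P(j ≤ a_C); in both
    cases j ~ Binomial(a_C + s_C, P_A) and the observed value is included.
    Fractional counts are handled through the incomplete-beta identity.
    Degenerate P_A ∈ {0, 1} yields the point-mass tail with a warning.
    """
    if direction not in ("rapid", "slow"):
        raise ValueError(f"direction must be 'rapid' or 'slow', got {direction!r}")
    if a_C < 0 or s_C < 0 or (a_C == 0 and s_C == 0):
        raise ValueError("need non-negative counts, not both zero")
    if not 0.0 <= P_A <= 1.0:
        raise ValueError(f"P_A={P_A} outside [0, 1]")
    if P_A in (0.0, 1.0):
        logger.warning("degenerate P_A=%s; tail probability is 0/1", P_A)
        if direction == "rapid":  # all mass at j = n·P_A ∈ {0, n}
            return 1.0 if (P_A == 1.0 or a_C <= 0) else 0.0
        return 1.0 if (P_A == 0.0 or s_C <= 0) else 0.0
    fn = _p_rapid_arr if direction == "rapid" else _p_slow_arr
    return float(fn(np.array([a_C]), np.array([s_C]), np.array([P_A]))[0])


def _counts_dict(counts: Iterable[SubstitutionCounts]) -> dict[str, SubstitutionCounts]:
    d: dict[str, SubstitutionCounts] = {}
    for c in counts:
        if c.gene_id in d:
            raise ValueError(f"duplicate counts record for gene {c.gene_id}")
        d[c.gene_id] = c
    return d


def test_all_categories(
    counts: Iterable[SubstitutionCounts],
    categories: Iterable[GoCategory],
    rates: GenomeRates | None = None,
    min_genes: int = 20,
) -> list[CategoryResult]:
    """Evaluate both tails for every category.

    Category genes without a counts record are dropped with a logged count and
    the category re-checked against ``min_genes``.  ``rates`` defaults to
    genome_rates over the supplied counts.
    """
    by_gene = _counts_dict(counts)
    if rates is None:
        rates = genome_rates(by_gene.values())
    results: list[CategoryResult] = []
    for cat in categories:
        members = [by_gene[g] for g in cat.gene_ids if g in by_gene]
        missing = cat.n_genes - len(members)
        if missing:
            logger.info("%s: %d member gene(s) lack counts, dropped", cat.term_id, missing)
        if len(members) < min_genes:
            logger.info("%s: below min_genes after drop, skipped", cat.term_id)
            continue
        a_C = sum(m.a for m in members)
        s_C = sum(m.s for m in members)
        sum_A = sum(m.A for m in members)
        sum_S = sum(m.S for m in members)
        if sum_A <= 0 or sum_S <= 0 or (a_C == 0 and s_C == 0):
            logger.warning("%s: degenerate sums, skipped", cat.term_id)
            continue
        P_A = expected_nonsyn_proportion(sum_A, sum_S, rates)
        ka_C = a_C / sum_A
        ks_C = s_C / sum_S
        results.append(
            CategoryResult(
                term_id=cat.term_id,
                n_genes=len(members),
                a_C=a_C,
                s_C=s_C,
                sum_A=sum_A,
                sum_S=sum_S,
                ka_C=ka_C,
                ks_C=ks_C,
                ka_ks_C=ka_C / ks_C if ks_C > 0 else float("nan"),
                P_A=P_A,
                p_rapid=tail_probability(a_C, s_C, P_A, "rapid"),
                p_slow=tail_probability(a_C, s_C, P_A, "slow"),
            )
        )
    return results


def count_outliers(results: Iterable[CategoryResult], threshold: float, direction: str) -> int:
    """Number of categories with the direction's tail probability strictly below threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    attr = "p_rapid" if direction == "rapid" else "p_slow"
    return sum(1 for r in results if getattr(r, attr) < threshold)


def _membership_matrix(
    categories: Sequence[GoCategory], gene_index: dict[str, int]
) -> sparse.csr_matrix:
    rows, cols = [], []
    for i, cat in enumerate(categories):
        for g in cat.gene_ids:
            rows.append(i)
            cols.append(gene_index[g])
    data = np.ones(len(rows))
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(categories), len(gene_index))
    )


def _tails_from_sums(sums: np.ndarray, rates: GenomeRates) -> tuple[np.ndarray, np.ndarray]:
    """(p_rapid, p_slow) per category from a (n_cat, 4) array of (a, s, A, S) sums."""
    a, s, A, S = sums[:, 0], sums[:, 1], sums[:, 2], sums[:, 3]
    denom = rates.ka * A + rates.ks * S
    with np.errstate(invalid="ignore", divide="ignore"):
        pA = np.where(denom > 0, rates.ka * A / np.where(denom > 0, denom, 1.0), np.nan)
    ok = (denom > 0) & (a + s > 0) & (pA > 0) & (pA < 1)
    p_rapid = np.full(len(a), np.nan)
    p_slow = np.full(len(a), np.nan)
    if np.any(ok):
        p_rapid[ok] = _p_rapid_arr(a[ok], s[ok], pA[ok])
        p_slow[ok] = _p_slow_arr(a[ok], s[ok], pA[ok])
    return p_rapid, p_slow


def permutation_null(
    counts: Iterable[SubstitutionCounts],
    annotation: GoAnnotation,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    n_permutations: int = 10_000,
    seed: int | None = None,
    min_genes: int = 20,
    rates: GenomeRates | None = None,
    rng: np.random.Generator | None = None,
    exhaustive: bool = False,
) -> list[PermutationSummary]:
    """Annotation-permutation null for the outlier counts at each threshold.

    Whole per-gene term sets are re-assigned uniformly at random
    ``n_permutations`` times; after each re-assignment the categories are
    rebuilt (sizes are invariant, so the ≥min_genes filter is too) and both
    tails recomputed against the SAME genome rates, which are
    permutation-invariant.  Genes in the annotation universe without a counts
    record are removed once up front (logged) — they could never contribute
    to a category sum.

    With ``exhaustive=True`` all n! assignments are enumerated instead of
    sampled (only feasible for very small universes); no seed is needed and
    the expected counts are exact.

    Returns one PermutationSummary per (direction, threshold).
    """
    if not exhaustive:
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if rng is None:
            if seed is None:
                raise ValueError("a seed (or an explicit rng) is required")
            rng = np.random.default_rng(seed)
    by_gene = _counts_dict(counts)
    if rates is None:
        rates = genome_rates(by_gene.values())

    missing = [g for g in annotation.universe if g not in by_gene]
    if missing:
        logger.info("%d universe gene(s) lack counts; removed before permutation", len(missing))
        keep = [g for g in annotation.universe if g in by_gene]
        annotation = GoAnnotation({g: annotation[g] for g in keep}, keep)

    genes = annotation.universe
    n = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    categories = build_categories(annotation, min_genes=min_genes)
    if not categories:
        raise ValueError("no categories pass the size filter")
    M = _membership_matrix(categories, gene_index)
    X = np.array([[by_gene[g].a, by_gene[g].s, by_gene[g].A, by_gene[g].S] for g in genes])

    thresholds = tuple(thresholds)
    t_arr = np.array(thresholds)

    def outlier_counts(p_rapid: np.ndarray, p_slow: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pr = p_rapid[~np.isnan(p_rapid)]
        ps = p_slow[~np.isnan(p_slow)]
        return (pr[:, None] < t_arr).sum(axis=0), (ps[:, None] < t_arr).sum(axis=0)

    obs_rapid, obs_slow = outlier_counts(*_tails_from_sums(M @ X, rates))

    if exhaustive:
        import itertools
        import math as _math

        if _math.factorial(n) > 50_000:
            raise ValueError(f"exhaustive enumeration infeasible for {n} genes")
        perms = [np.array(p) for p in itertools.permutations(range(n))]
        n_permutations = len(perms)
    else:
        perms = None

    perm_rapid = np.empty((n_permutations, len(thresholds)), dtype=np.int64)
    perm_slow = np.empty_like(perm_rapid)
    for k in range(n_permutations):
        perm = perms[k] if perms is not None else rng.permutation(n)
        cr, cs = outlier_counts(*_tails_from_sums(M @ X[perm], rates))
        perm_rapid[k] = cr
        perm_slow[k] = cs

    out: list[PermutationSummary] = []
    for direction, obs, mat in (("rapid", obs_rapid, perm_rapid), ("slow", obs_slow, perm_slow)):
        for j, t in enumerate(thresholds):
            ge = int((mat[:, j] >= obs[j]).sum())
            # add-one estimator under sampling; exact proportion when enumerated
            gp = ge / n_permutations if exhaustive else (1 + ge) / (1 + n_permutations)
            out.append(
                PermutationSummary(
                    direction=direction,
                    threshold=t,
                    observed_count=int(obs[j]),
                    expected_count=float(mat[:, j].mean()),
                    sd_count=float(mat[:, j].std()),
                    global_p=gp,
                    plain_p=ge / n_permutations,
                    n_permutations=n_permutations,
                    seed=seed,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------


class CategoryDivergenceModel:
    """Category-level divergence model over per-gene substitution counts and a
    gene→GO annotation.

    Parameters
    ----------
    counts
        Per-gene SubstitutionCounts (the ortholog universe T).  Unusable
        records (zero sites) are rejected.
    annotation
        GoAnnotation over (a subset of) the counts universe; a plain
        ``{gene: terms}`` mapping is also accepted and is interpreted over the
        full counts universe, unannotated genes carrying empty sets.
    min_genes
        Category size filter (default 20).

    Examples
    --------
    >>> model = CategoryDivergenceModel(counts, {"g1": {"GO:1"}, ...})
    >>> res = model.fit(n_permutations=1000, seed=7)
    >>> print(res.summary())
    """

    def __init__(
        self,
        counts: Iterable[SubstitutionCounts],
        annotation: GoAnnotation | dict | None = None,
        *,
        min_genes: int = 20,
    ) -> None:
        self.counts = [c for c in counts if c.usable]
        if not self.counts:
            raise ValueError("no usable substitution counts")
        self.min_genes = min_genes
        universe = [c.gene_id for c in self.counts]
        if annotation is None:
            annotation = GoAnnotation({}, universe)
        elif isinstance(annotation, dict):
            annotation = GoAnnotation(annotation, universe)
        self.annotation = annotation
        self.rates = genome_rates(self.counts)

    @classmethod
    def from_files(
        cls,
        counts_path: str | Path,
        annotation_path: str | Path,
        *,
        namespace: str | None = None,
        min_genes: int = 20,
    ) -> "CategoryDivergenceModel":
        """Build from a counts TSV (gene_id, a, A, s, S) and an annotation TSV."""
        counts = read_counts_table(counts_path)
        universe = [c.gene_id for c in counts if c.usable]
        annotation = read_annotation(annotation_path, universe, namespace=namespace)
        model = cls(counts, annotation, min_genes=min_genes)
        model._input_digests = {
            "counts": _file_digest(counts_path),
            "annotation": _file_digest(annotation_path),
        }
        return model

    _input_digests: dict[str, str] | None = None

    def fit(
        self,
        thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
        n_permutations: int | None = 10_000,
        seed: int | None = None,
    ) -> "CategoryDivergenceResults":
        """Evaluate every category and (optionally) the permutation null.

        ``n_permutations=None`` (or 0) skips the permutation stage; otherwise
        a ``seed`` is required for reproducibility.
        """
        categories = build_categories(self.annotation, min_genes=self.min_genes)
        results = test_all_categories(
            self.counts, categories, rates=self.rates, min_genes=self.min_genes
        )
        summaries: list[PermutationSummary] = []
        if n_permutations:
            summaries = permutation_null(
                self.counts,
                self.annotation,
                thresholds=thresholds,
                n_permutations=n_permutations,
                seed=seed,
                min_genes=self.min_genes,
                rates=self.rates,
            )
        return CategoryDivergenceResults(
            model=self,
            category_results=results,
            permutation_summaries=summaries,
            thresholds=tuple(thresholds),
            seed=seed,
            n_permutations=n_permutations or 0,
        )


class CategoryDivergenceResults:
    """Fitted results: per-category statistics plus permutation summaries."""

    def __init__(
        self,
        model: CategoryDivergenceModel,
        category_results: list[CategoryResult],
        permutation_summaries: list[PermutationSummary],
        thresholds: tuple[float, ...],
        seed: int | None,
        n_permutations: int,
    ) -> None:
        self.model = model
        self.category_results = category_results
        self.permutation_summaries = permutation_summaries
        self.thresholds = thresholds
        self.seed = seed
        self.n_permutations = n_permutations

    @property
    def genome_rates(self) -> GenomeRates:
        return self.model.rates

    @property
    def category_table(self) -> pd.DataFrame:
        """Per-category results sorted by p_rapid ascending."""
        df = pd.DataFrame([asdict(r) for r in self.category_results])
        if df.empty:
            return pd.DataFrame(
                columns=[f.name for f in CategoryResult.__dataclass_fields__.values()]
            )
        return df.sort_values("p_rapid", kind="mergesort").reset_index(drop=True)

    @property
    def permutation_table(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(p) for p in self.permutation_summaries])

    def outliers(self, threshold: float, direction: str) -> int:
        return count_outliers(self.category_results, threshold, direction)

    def summary(self) -> str:
        """Human-readable report: observed vs expected outlier counts per
        threshold and direction, with the global permutation p-value."""
        r = self.genome_rates
        lines = [
            "Category divergence test",
            "=" * 60,
            f"genes in universe:     {r.n_genes}",
            f"categories tested:     {len(self.category_results)} (>= {self.model.min_genes} genes)",
            f"genome-wide ka:        {r.ka:.6g}",
            f"genome-wide ks:        {r.ks:.6g}",
            f"genome-wide ka/ks:     {r.ka / r.ks:.6g}" if r.ks > 0 else "genome-wide ka/ks: undefined",
        ]
        if self.permutation_summaries:
            lines += [
                "",
                f"permutation null:      {self.n_permutations} permutations, seed {self.seed}",
                f"{'direction':<9} {'threshold':>9} {'observed':>9} {'expected':>9} {'global P':>12}",
            ]
            for s in self.permutation_summaries:
                lines.append(
                    f"{s.direction:<9} {s.threshold:>9g} {s.observed_count:>9d} "
                    f"{s.expected_count:>9.2f} {s.global_p:>12.4g}"
                )
        else:
            lines += ["", "observed outlier counts (no permutation null run):"]
            for direction in ("rapid", "slow"):
                for t in self.thresholds:
                    lines.append(
                        f"  {direction:<6} P < {t:<7g}: {self.outliers(t, direction)} categories"
                    )
        return "\n".join(lines)

    def plot_pvalue_histogram(self, direction: str = "rapid", ax=None):
        """Histogram of per-category tail probabilities (diagnostic)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        attr = "p_rapid" if direction == "rapid" else "p_slow"
        ax.hist([getattr(r, attr) for r in self.category_results], bins=20, range=(0, 1))
        ax.set_xlabel(f"per-category tail probability ({direction})")
        ax.set_ylabel("categories")
        return ax

    def to_files(self, outdir: str | Path, prefix: str = "category_test") -> dict[str, Path]:
        """Write category results TSV, permutation summary TSV and run-metadata JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["categories"] = outdir / f"{prefix}.categories.tsv"
        self.category_table.to_csv(paths["categories"], sep="\t", index=False, float_format="%.6g")
        if self.permutation_summaries:
            paths["permutation"] = outdir / f"{prefix}.permutation.tsv"
            self.permutation_table.to_csv(
                paths["permutation"], sep="\t", index=False, float_format="%.6g"
            )
        meta = {
            "seed": self.seed,
            "n_permutations": self.n_permutations,
            "thresholds": list(self.thresholds),
            "min_genes": self.model.min_genes,
            "n_genes": self.genome_rates.n_genes,
            "n_categories": len(self.category_results),
            "genome_ka": self.genome_rates.ka,
            "genome_ks": self.genome_rates.ks,
            "input_digests": self.model._input_digests,
        }
        paths["metadata"] = outdir / f"{prefix}.meta.json"
        paths["metadata"].write_text(json.dumps(meta, indent=2) + "\n")
        return paths


def _file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
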