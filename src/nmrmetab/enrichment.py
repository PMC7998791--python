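"""Quantitative metabolite set enrichment analysis (QMSEA).

A global-test style quantitative enrichment: for each metabolite set, a
generalized-linear-model Q statistic measures the association between the
member metabolite profiles and the binary outcome; the set Q is the mean
of the member statistics, significance comes from outcome permutation,
and Holm-Bonferroni adjustment controls multiplicity across sets.

With standardized metabolite columns x_i and centered outcome z = y - ybar,
the per-metabolite statistic reduces to Q_i = (x_i' z)^2 / (sigma^2 x_i'x_i)
with sigma^2 = z'z/n, i.e. Q_i = n r_i^2 where r_i is the Pearson
correlation between metabolite i and the outcome.

Chemically heterogeneous envelope signals (lipoprotein triacylglycerols,
acute-phase glycoprotein resonances, the protein aromatic residue signal,
creatine/phosphocreatine) are excluded from mapping by default.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Heterogeneous signals never mapped into metabolite sets.
DEFAULT_EXCLUSIONS = ("Total TAGs", "APG-I", "APG-II", "PAAR", "Cr/PCr")

CATEGORIES = ("pathway", "predicted", "location")


class GmtParseError(ValueError):
    pass


@dataclass(frozen=True)
class MetaboliteSet:
    name: str
    category: str
    members: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise ValueError("metabolite set must be nonempty")


@dataclass
class EnrichmentResult:
    set_name: str
    category: str
    total: int  # metabolites in the set
    hits: int  # members measured in the data
    hit_names: tuple[str, ...]
    q: float
    member_q: dict[str, float]
    p: float
    p_adj: float | None = None


def load_gmt(path, category: str = "pathway") -> list[MetaboliteSet]:
    """Read a GMT library (name <tab> description <tab> members...)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise GmtParseError(f"unreadable GMT line {lineno}: {line[:60]!r}")
            name, _desc, *members = parts
            members = [m.strip() for m in members if m.strip()]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                logger.warning("set %r: duplicate members collapsed", name)
            if not unique:
                logger.warning("set %r is empty; skipped", name)
                continue
            sets.append(MetaboliteSet(name=name, category=category, members=tuple(unique)))
    return sets


def save_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.category, *s.members]) + "\n")


def bundled_pathway_library() -> list[MetaboliteSet]:
    """Small synthetic pathway-set library bundled for testing.

    Set names follow the common metabolic-pathway vocabulary; member lists
    are plausible but synthetic stand-ins, not the proprietary 99-entry
    library.  Users supply real GMT files for production analyses.
    """
    with resources.as_file(
        resources.files("nmrmetab.data") / "pathway_sets.synthetic.gmt"
    ) as p:
        return load_gmt(p, category="pathway")


def load_synonyms(path=None) -> dict[str, str]:
    """Synonym map (lower-cased alias -> canonical measured name)."""
    if path is None:
        ctx = resources.as_file(resources.files("nmrmetab.data") / "synonyms.csv")
        with ctx as p:
            return load_synonyms(p)
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if len(row) >= 2 and row[0].strip():
                out[row[0].strip().lower()] = row[1].strip()
    return out


def map_metabolites(
    measured,
    library,
    exclusions=DEFAULT_EXCLUSIONS,
    synonyms: dict[str, str] | None = None,
) -> dict[str, list[str]]:
    """Per-set hit lists: set members matched to measured metabolite names.

    Matching is case-insensitive exact, extended by the synonym map;
    excluded (heterogeneous) signals are removed from the measured panel
    before matching.  Unmatched member names are logged.
    """
    synonyms = {} if synonyms is None else {k.lower(): v for k, v in synonyms.items()}
    excluded_lower = {e.lower() for e in exclusions}
    canon = {}
    for name in measured:
        if name.lower() in excluded_lower:
            continue
        canon[name.lower()] = name
    hits: dict[str, list[str]] = {}
    for s in library:
        found = []
        for member in s.members:
            key = member.lower()
            key = synonyms.get(key, member).lower() if key in synonyms else key
            if key in canon and canon[key] not in found:
                found.append(canon[key])
        if not found:
            logger.info("set %r: no measured members", s.name)
        hits[s.name] = found
    return hits


def globaltest_q(X_set, y) -> tuple[dict[str, float], float]:
    """Global-test Q statistics for one metabolite set.

    Returns (per-metabolite Q, set Q); the set statistic is the arithmetic
    mean of the member statistics.  Zero-variance metabolites get Q = 0.
    """
    df = X_set if isinstance(X_set, pd.DataFrame) else pd.DataFrame(X_set)
    if df.shape[1] < 1:
        raise ValueError("need at least one member metabolite")
    y01 = np.asarray(y)
    classes = np.unique(y01)
    if classes.size != 2:
        raise ValueError("both classes must be present")
    z = (y01 == classes[1]).astype(float)
    z = z - z.mean()
    n = z.size
    sigma2 = (z @ z) / n
    member_q = {}
    for name in df.columns:
        x = df[name].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            logger.warning("metabolite %r has zero variance; Q = 0", name)
            member_q[name] = 0.0
            continue
        xs = (x - x.mean()) / sd
        member_q[name] = float((xs @ z) ** 2 / (sigma2 * (xs @ xs)))
    set_q = float(np.mean(list(member_q.values())))
    return member_q, set_q


def globaltest_p(
    q_observed: float,
    X_set,
    y,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value for a set Q statistic (add-one convention)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(0) if rng is None else rng
    df = X_set if isinstance(X_set, pd.DataFrame) else pd.DataFrame(X_set)
    X = df.to_numpy(dtype=float)
    sd = X.std(axis=0)
    ok = sd > 0
    Xs = np.zeros_like(X)
    Xs[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    y01 = np.asarray(y)
    classes = np.unique(y01)
    z = (y01 == classes[1]).astype(float)
    z = z - z.mean()
    n = z.size
    sigma2 = (z @ z) / n
    denom = (Xs**2).sum(axis=0)
    denom[~ok] = np.inf  # zero-variance members contribute Q = 0
    # permuted z has the same sigma2; vectorize over permutations
    Z = np.column_stack([rng.permutation(z) for _ in range(n_perm)])
    proj = Xs.T @ Z  # members x perms
    q_null = (proj**2 / (sigma2 * denom[:, None])).mean(axis=0)
    count = int((q_null >= q_observed - 1e-12).sum())
    return (1 + count) / (n_perm + 1)


def holm_bonferroni(p_values) -> np.ndarray:
    """Step-down Holm adjustment with monotonicity enforcement and cap at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    # step-down: (m - rank) * p, nondecreasing in sorted order, capped at 1
    adj_sorted = np.minimum(
        np.maximum.accumulate((m - np.arange(m)) * p[order]), 1.0
    )
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def enrich(
    matrix,
    y=None,
    library=None,
    exclusions=DEFAULT_EXCLUSIONS,
    synonyms: dict[str, str] | None = None,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
) -> list[EnrichmentResult]:
    """Run QMSEA over a library against a sample x metabolite matrix.

    Sets without any measured member are omitted (logged); the remaining
    sets get a permutation p-value for their mean-member Q, Holm-adjusted
    across tested sets; results are sorted by adjusted then raw p.
    """
    if library is None or not library:
        raise ValueError("nonempty metabolite set library required")
    df = matrix.to_frame() if hasattr(matrix, "to_frame") else pd.DataFrame(matrix)
    if y is None and hasattr(matrix, "groups") and matrix.groups is not None:
        y = matrix.groups
    rng = np.random.default_rng(0) if rng is None else rng
    hits = map_metabolites(df.columns, library, exclusions, synonyms)
    results = []
    for s in library:
        members = hits.get(s.name, [])
        if not members:
            logger.info("set %r omitted: no hits", s.name)
            continue
        member_q, set_q = globaltest_q(df[members], y)
        p = globaltest_p(set_q, df[members], y, n_perm=n_perm, rng=rng)
        results.append(
            EnrichmentResult(
                set_name=s.name,
                category=s.category,
                total=len(s.members),
                hits=len(members),
                hit_names=tuple(members),
                q=set_q,
                member_q=member_q,
                p=p,
            )
        )
    if not results:
        logger.warning("no set had any measured member; empty result")
        return []
    adj = holm_bonferroni([r.p for r in results])
    for r, a in zip(results, adj):
        r.p_adj = float(a)
    results.sort(key=lambda r: (r.p_adj, r.p))
    return results


def results_frame(results) -> pd.DataFrame:
    """Tidy table: set, total metabolites, hits, Q statistic, adjusted p."""
    return pd.DataFrame(
        [
            {
                "set": r.set_name,
                "category": r.category,
                "total_metabolites": r.total,
                "hits": r.hits,
                "q_statistic": r.q,
                "p": r.p,
                "p_fdr": r.p_adj,
            }
            for r in results
        ]
    ).set_index("set")
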