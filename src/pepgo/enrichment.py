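"""Between-run GO enrichment.

For each GO term observed in either of two runs, the term's share of
the run's total bacterial spectra is compared between runs with a
pooled two-sample z-test of proportions (no continuity correction), and
effect size is reported as the log2 fold change of Laplace-corrected
(add-one) proportions:

    log2FC = log2( ((c_b + 1)/(N_b + 1)) / ((c_a + 1)/(N_a + 1)) )

Raw p-values receive a Bonferroni correction over the tested family
(terms observed in either run).  A term is called significant when it
is *terminal* — no more-specific term in the tested set — and its
corrected p-value clears ``alpha`` (default 0.01).  Testing only
terminal terms avoids redundant calls on ancestors whose counts are
sums of their descendants'.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, IntegrityError
from .ontology import GoDag
from .quantify import GoCountTable


def _validate_pair(count, total) -> None:
    count = np.asarray(count)
    total = np.asarray(total)
    if np.any(count < 0) or np.any(total < np.maximum(count, 1)):
        raise InputError(
            "need total >= count >= 0 and total >= 1 "
            f"(got count={count}, total={total})"
        )


def laplace_log2fc(count_a, total_a, count_b, total_b):
    """Add-one-corrected log2 fold change of run B relative to run A.

    Finite for all legal inputs, including zero counts; antisymmetric
    under swapping runs.  Accepts scalars or arrays.
    """
    _validate_pair(count_a, total_a)
    _validate_pair(count_b, total_b)
    ca = np.asarray(count_a, dtype=float)
    cb = np.asarray(count_b, dtype=float)
    na = np.asarray(total_a, dtype=float)
    nb = np.asarray(total_b, dtype=float)
    out = np.log2((cb + 1.0) / (nb + 1.0)) - np.log2((ca + 1.0) / (na + 1.0))
    return float(out) if out.ndim == 0 else out


def proportion_test(count_a, total_a, count_b, total_b):
    """Two-tailed pooled z-test of proportions.

    z = (p_a - p_b) / sqrt(p(1-p)(1/N_a + 1/N_b)) with p the pooled
    proportion; p-value = 2*(1 - Phi(|z|)).  Returns 1.0 when the
    pooled proportion is degenerate (0 or 1).  Accepts scalars or
    arrays.
    """
    _validate_pair(count_a, total_a)
    _validate_pair(count_b, total_b)
    ca = np.asarray(count_a, dtype=float)
    cb = np.asarray(count_b, dtype=float)
    na = np.asarray(total_a, dtype=float)
    nb = np.asarray(total_b, dtype=float)
    pooled = (ca + cb) / (na + nb)
    var = pooled * (1.0 - pooled) * (1.0 / na + 1.0 / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (ca / na - cb / nb) / np.sqrt(var)
    p = np.where(var > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    return float(p) if p.ndim == 0 else p


def terminal_terms(dag: GoDag, observed: Iterable[str]) -> set[str]:
    """Members of ``observed`` with no strict descendant also in
    ``observed`` — the most specific terms of the set."""
    observed = set(observed)
    for tid in observed:
        if tid not in dag:
            raise KeyError(f"unknown GO term: {tid!r}")
    non_terminal: set[str] = set()
    for tid in observed:
        non_terminal |= dag.ancestors(tid) & observed
    return observed - non_terminal


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-term comparison outcome between two runs (B relative to A)."""

    go_id: str
    count_a: int
    total_a: int
    count_b: int
    total_b: int
    log2fc: float
    p_raw: float
    p_bonf: float
    is_terminal: bool
    is_significant: bool


def compare_runs(
    table_a: GoCountTable,
    table_b: GoCountTable,
    dag: GoDag,
    alpha: float = 0.01,
    terminal_mode: str = "observed",
) -> list[EnrichmentResult]:
    """Full enrichment comparison of two runs' GO count tables.

    The tested family is the union of terms with nonzero count in
    either run; Bonferroni multiplies by its size.  ``terminal_mode``
    selects whether terminality is judged against the tested set
    (``"observed"``, default) or against the full ontology's leaves
    (``"ontology"``).  Results are sorted by corrected p-value, ties
    broken by GO id.
    """
    if terminal_mode not in ("observed", "ontology"):
        raise InputError(f"unknown terminal_mode: {terminal_mode!r}")
    tested = sorted(
        {t for t, c in table_a.counts.items() if c > 0}
        | {t for t, c in table_b.counts.items() if c > 0}
    )
    missing = [t for t in tested if t not in dag]
    if missing:
        raise IntegrityError(
            f"count tables contain terms absent from the ontology: {missing[:5]}"
        )
    if not tested:
        return []
    m = len(tested)
    ca = np.array([table_a.counts.get(t, 0) for t in tested], dtype=np.int64)
    cb = np.array([table_b.counts.get(t, 0) for t in tested], dtype=np.int64)
    na, nb = table_a.total_spectra, table_b.total_spectra
    if na < ca.max() or nb < cb.max() or na < 1 or nb < 1:
        raise IntegrityError("count table total smaller than a term count")
    lfc = laplace_log2fc(ca, na, cb, nb)
    p_raw = proportion_test(ca, na, cb, nb)
    p_bonf = np.minimum(1.0, m * p_raw)
    if terminal_mode == "observed":
        terminal = terminal_terms(dag, tested)
    else:
        terminal = {t for t in tested if dag.is_leaf(t)}
    results = [
        EnrichmentResult(
            go_id=t,
            count_a=int(a),
            total_a=na,
            count_b=int(b),
            total_b=nb,
            log2fc=float(f),
            p_raw=float(pr),
            p_bonf=float(pb),
            is_terminal=t in terminal,
            is_significant=bool(t in terminal and pb < alpha),
        )
        for t, a, b, f, pr, pb in zip(tested, ca, cb, lfc, p_raw, p_bonf)
    ]
    results.sort(key=lambda r: (r.p_bonf, r.go_id))
    return results


class GoEnrichment:
    """Model object: enrichment comparison of two runs.

    Parameters mirror :func:`compare_runs`; :meth:`fit` performs the
    comparison and returns a :class:`GoEnrichmentResults`.
    """

    def __init__(
        self,
        table_a: GoCountTable,
        table_b: GoCountTable,
        dag: GoDag,
        alpha: float = 0.01,
        terminal_mode: str = "observed",
    ):
        self.table_a = table_a
        self.table_b = table_b
        self.dag = dag
        self.alpha = alpha
        self.terminal_mode = terminal_mode

    def fit(self) -> "GoEnrichmentResults":
        results = compare_runs(
            self.table_a,
            self.table_b,
            self.dag,
            alpha=self.alpha,
            terminal_mode=self.terminal_mode,
        )
        return GoEnrichmentResults(self, results)


class GoEnrichmentResults:
    """Fitted enrichment comparison with tabular and text views."""

    def __init__(self, model: GoEnrichment, results: Sequence[EnrichmentResult]):
        self.model = model
        self.results = list(results)

    @property
    def significant(self) -> list[EnrichmentResult]:
        return [r for r in self.results if r.is_significant]

    @property
    def n_tested(self) -> int:
        return len(self.results)

    def frame(self, dag: GoDag | None = None) -> pd.DataFrame:
        """Results as a DataFrame (sorted by p_bonf, then GO id)."""
        dag = dag or self.model.dag
        rows = [
            {
                "go_id": r.go_id,
                "name": dag[r.go_id].name,
                "aspect": dag.aspect_of(r.go_id),
                "count_a": r.count_a,
                "count_b": r.count_b,
                "log2fc": r.log2fc,
                "p_raw": r.p_raw,
                "p_bonf": r.p_bonf,
                "terminal": r.is_terminal,
                "significant": r.is_significant,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)

    def summary(self, max_rows: int = 20) -> str:
        a, b = self.model.table_a, self.model.table_b
        lines = [
            "GO enrichment (two-tailed test of proportions, "
            "Bonferroni-corrected)",
            f"  run A: {a.run_id} ({a.total_spectra} spectra)   "
            f"run B: {b.run_id} ({b.total_spectra} spectra)",
            f"  tested terms: {self.n_tested}   alpha: {self.model.alpha}   "
            f"significant terminal terms: {len(self.significant)}",
        ]
        sig = self.significant[:max_rows]
        if sig:
            lines.append(f"  {'go_id':<12} {'log2fc':>8} {'p_bonf':>12}")
            for r in sig:
                lines.append(
                    f"  {r.go_id:<12} {r.log2fc:>8.3f} {r.p_bonf:>12.3e}"
                )
        return "\n".join(lines)
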