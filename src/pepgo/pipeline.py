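"""End-to-end orchestration: annotate -> filter -> quantify -> enrich ->
rate matrices -> permutation test -> concordance.

The pipeline is a pure function of (inputs, options, seed): rerunning
with the same manifest and seed reproduces every output file.  All
stage outputs are plain TSVs next to a machine-readable summary.json.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from .annotate import annotate_peptides, filter_nonbacterial
from .concordance import pooled_concordance
from .dynamics import RateChangeTest, build_ratio_matrix
from .enrichment import GoEnrichment
from .errors import InputError
from .matching import index_proteins
from .ontology import parse_obo
from .quantify import class_abundance, go_spectral_counts
from .taxonomy import parse_taxonomy

logger = logging.getLogger(__name__)


@dataclass
class ReferencePaths:
    fasta: Path
    annotations: Path
    taxonomy: Path
    obo: Path


@dataclass
class RunSpec:
    run_id: str
    day: float
    psm: Path
    otu: Path | None = None


@dataclass
class RunManifest:
    """One experiment: an ordered set of runs sharing a treatment."""

    experiment: str
    site: str
    treatment: str
    runs: list[RunSpec] = field(default_factory=list)

    def __post_init__(self):
        days = [r.day for r in self.runs]
        if len(set(days)) != len(days):
            raise InputError(
                f"experiment {self.experiment}: duplicate days in manifest"
            )


def load_manifest(path) -> tuple[ReferencePaths, list[RunManifest]]:
    """Load manifest.yaml; relative paths resolve against its directory."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    base = path.parent

    def resolve(p):
        return base / p

    try:
        ref = ReferencePaths(
            fasta=resolve(doc["reference"]["fasta"]),
            annotations=resolve(doc["reference"]["annotations"]),
            taxonomy=resolve(doc["reference"]["taxonomy"]),
            obo=resolve(doc["reference"]["obo"]),
        )
        manifests = []
        for exp in doc["experiments"]:
            runs = [
                RunSpec(
                    run_id=r["run_id"],
                    day=float(r["day"]),
                    psm=resolve(r["psm"]),
                    otu=resolve(r["otu"]) if r.get("otu") else None,
                )
                for r in exp["runs"]
            ]
            manifests.append(
                RunManifest(
                    experiment=exp["experiment"],
                    site=exp.get("site", ""),
                    treatment=exp.get("treatment", ""),
                    runs=sorted(runs, key=lambda r: r.day),
                )
            )
    except KeyError as exc:
        raise InputError(f"manifest missing key: {exc}") from exc
    for m in manifests:
        for r in m.runs:
            if not r.psm.exists():
                raise InputError(f"missing PSM file: {r.psm}")
    return ref, manifests


def run_pipeline(
    reference: ReferencePaths,
    manifests: list[RunManifest],
    outdir,
    alpha: float = 0.01,
    n_perm: int = 10_000,
    seed: int = 0,
    rate_days: tuple[float, ...] | None = (0.0, 1.0, 6.0),
    rate_mode: str = "mean",
    perm_mode: str = "rows",
    terminal_mode: str = "observed",
    keep_untaxed: bool = False,
    il_equivalence: bool = True,
    include_part_of: bool = True,
) -> dict:
    """Execute all stages; returns (and writes) the summary dict.

    ``rate_days`` restricts the ratio matrices to a day grid (default
    {0, 1, 6}); runs at other days still enter quantification and
    enrichment.  Enrichment compares sequential time points within each
    experiment.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("pepgo")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(
            reference, manifests, out, alpha, n_perm, seed, rate_days,
            rate_mode, perm_mode, terminal_mode, keep_untaxed,
            il_equivalence, include_part_of,
        )
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(
    reference, manifests, out, alpha, n_perm, seed, rate_days,
    rate_mode, perm_mode, terminal_mode, keep_untaxed,
    il_equivalence, include_part_of,
) -> dict:
    logger.info(
        "options: alpha=%s n_perm=%s seed=%s rate_days=%s rate_mode=%s "
        "perm_mode=%s terminal_mode=%s",
        alpha, n_perm, seed, rate_days, rate_mode, perm_mode, terminal_mode,
    )
    dag = parse_obo(str(reference.obo), include_part_of=include_part_of)
    tree = parse_taxonomy(str(reference.taxonomy))
    proteins = pio.load_proteins(reference.fasta, reference.annotations)
    matcher = index_proteins(proteins, il_equivalence=il_equivalence)

    observations = {}
    for m in manifests:
        for r in m.runs:
            observations[r.run_id] = pio.read_psm_table(r.psm)
    all_peptides = sorted(
        {o.peptide for obs in observations.values() for o in obs}
    )
    annotations = annotate_peptides(
        dag, tree, proteins, matcher, all_peptides, keep_untaxed=keep_untaxed
    )
    matched = [a for a in annotations.values() if a.protein_ids]
    kept, removed = filter_nonbacterial(matched)
    kept_map = {a.peptide: a for a in kept}
    logger.info(
        "peptides: %d observed, %d matched, %d bacterial kept, %d removed",
        len(all_peptides), len(matched), len(kept), removed,
    )

    summary: dict = {
        "seed": seed,
        "alpha": alpha,
        "n_peptides_observed": len(all_peptides),
        "n_peptides_matched": len(matched),
        "n_peptides_bacterial": len(kept),
        "n_nonbacterial_removed": removed,
        "experiments": {},
    }

    count_tables = {}
    class_tables = {}
    count_rows, class_rows = [], []
    for m in manifests:
        for r in m.runs:
            obs = [o for o in observations[r.run_id] if o.peptide in kept_map]
            table = go_spectral_counts(kept_map, obs, r.run_id)
            count_tables[r.run_id] = table
            classes = class_abundance(kept_map, obs, r.run_id, tree)
            class_tables[r.run_id] = classes
            count_rows += [
                (r.run_id, gid, c, table.total_spectra)
                for gid, c in sorted(table.counts.items())
            ]
            class_rows += [
                (r.run_id, cls, frac) for cls, frac in sorted(classes.items())
            ]
    pd.DataFrame(
        count_rows, columns=["run_id", "go_id", "count", "total"]
    ).to_csv(out / "go_counts.tsv", sep="\t", index=False)
    pd.DataFrame(
        class_rows, columns=["run_id", "class", "fraction"]
    ).to_csv(out / "class_abundance.tsv", sep="\t", index=False)

    for m in manifests:
        exp: dict = {"treatment": m.treatment, "runs": [r.run_id for r in m.runs]}
        summary["experiments"][m.experiment] = exp

        # ---- sequential enrichment -----------------------------------
        comparisons = []
        if len(m.runs) < 2:
            logger.info(
                "experiment %s has a single run: enrichment skipped",
                m.experiment,
            )
        for ra, rb in zip(m.runs, m.runs[1:]):
            res = GoEnrichment(
                count_tables[ra.run_id],
                count_tables[rb.run_id],
                dag,
                alpha=alpha,
                terminal_mode=terminal_mode,
            ).fit()
            name = f"{ra.run_id}_vs_{rb.run_id}"
            res.frame().to_csv(
                out / f"enrichment_{m.experiment}_{name}.tsv",
                sep="\t", index=False,
            )
            comparisons.append(
                {
                    "pair": name,
                    "n_tested": res.n_tested,
                    "n_significant": len(res.significant),
                    "significant_terms": sorted(
                        r.go_id for r in res.significant
                    ),
                }
            )
        exp["comparisons"] = comparisons

        # ---- rate matrices and permutation test ----------------------
        sig_terms = sorted(
            {t for c in comparisons for t in c["significant_terms"]}
        )
        runs_for_rates = [
            r for r in m.runs
            if rate_days is None or r.day in set(rate_days)
        ]
        exp["n_significant_union"] = len(sig_terms)
        if len(runs_for_rates) >= 2 and sig_terms:
            func_per_run = [
                (
                    r.day,
                    {
                        t: count_tables[r.run_id].counts.get(t, 0)
                        / count_tables[r.run_id].total_spectra
                        for t in sig_terms
                    },
                )
                for r in runs_for_rates
            ]
            tax_per_run = [
                (
                    r.day,
                    {
                        c: f
                        for c, f in class_tables[r.run_id].items()
                        if c != "Unclassified"
                    },
                )
                for r in runs_for_rates
            ]
            func_matrix = build_ratio_matrix(func_per_run)
            tax_matrix = build_ratio_matrix(tax_per_run)
            pio.write_ratio_matrix(
                func_matrix, out / f"ratios_functional_{m.experiment}.tsv"
            )
            pio.write_ratio_matrix(
                tax_matrix, out / f"ratios_taxonomic_{m.experiment}.tsv"
            )
            perm = RateChangeTest(
                func_matrix, tax_matrix,
                rate_mode=rate_mode, perm_mode=perm_mode,
            ).fit(n_perm=n_perm, seed=seed)
            exp["rates"] = {
                "functional_mean_rate_per_day": perm.func_mean_rate,
                "n_functional_rows": perm.n_func,
                "taxonomic_mean_rate_per_day": perm.tax_mean_rate,
                "n_taxonomic_rows": perm.n_tax,
                "observed_diff": perm.observed_diff,
                "permutation_p": perm.p_value,
                "n_perm": perm.n_perm,
            }
        else:
            logger.info(
                "experiment %s: rate analysis skipped "
                "(need >=2 runs on the rate-day grid and >=1 significant term)",
                m.experiment,
            )

        # ---- concordance against 16S ----------------------------------
        otu_runs = {
            r.run_id: r.otu for r in m.runs if r.otu and Path(r.otu).exists()
        }
        if otu_runs:
            otu_tables = {}
            for run_id, p in otu_runs.items():
                otu_tables.update(pio.read_otu_table(p))
            peptide_tables = {
                run_id: class_tables[run_id] for run_id in otu_runs
            }
            try:
                r_val, p_val, n_val = pooled_concordance(
                    peptide_tables, otu_tables
                )
                exp["concordance"] = {"r": r_val, "p": p_val, "n": n_val}
            except InputError as exc:
                logger.warning(
                    "experiment %s: concordance skipped (%s)", m.experiment, exc
                )

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
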