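"""End-to-end orchestration of the synthetic immune-selection analysis.

The default pipeline generates a synthetic cohort with known selection
truth, scores every patient x mutation pair for class I and class II
presentation, runs the group comparisons and permutation control, fits the
four selection models, and writes the auxiliary signature and expression
analyses — all into one output directory with a machine-readable manifest
recording versions, seeds, the config hash, and the generative truth next
to the recovered estimates so parameter recovery can be audited.

All randomness flows from a single root seed split into named per-stage
streams; running the same config twice produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from . import __version__, glmm, signatures as sigmod, stats as statsmod
from ._rng import child_seed
from .expression import fit_expression_classifier
from .hla import (
    allele_frequencies,
    assemble_molecules,
    genotype_frequency_correlation,
    write_genotypes,
)
from .peptides import SyntheticRankBackend
from .phbr import PHBRMatrix, score_matrix
from .simulate import (
    CohortConfig,
    DriverCatalogConfig,
    SelectionTruth,
    generate_cohort,
    generate_driver_catalog,
    simulate_expression,
    simulate_mutations,
    simulate_signature_activities,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a full synthetic pipeline run."""

    seed: int = 0
    n_patients: int = 200
    n_mutations: int = 100
    sex_fraction_female: float = 0.5
    truth: SelectionTruth = field(default_factory=lambda: SelectionTruth(
        beta1=0.048, beta2=0.31, beta3=-0.02, beta4=0.07, beta5=0.15,
        theta_eta=0.3, intercept=-2.5,
    ))
    covariate: Literal["sex", "age"] = "sex"
    n_perm: int = 1000
    equations: tuple[int, ...] = (1, 2, 3, 4)
    signature_sex_bias: Mapping[str, float] = field(default_factory=lambda: {"02": 2.0})
    out_dir: str = "results"

    def to_dict(self) -> dict:
        """Analysis-relevant config (excludes output placement)."""
        d = asdict(self)
        d.pop("out_dir")  # runtime placement; not part of the analysis identity
        d["truth"] = asdict(self.truth)
        d["equations"] = list(self.equations)
        d["signature_sex_bias"] = dict(self.signature_sex_bias)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write(frame: pd.DataFrame, path: Path, **kwargs) -> None:
    frame.to_csv(path, sep="\t", float_format="%.10g", **kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to the out dir).

    A stage failure marks the bundle partial, records the failing stage's
    diagnostics in the manifest, and still writes everything produced so far.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seeds": {},
        "stages": {},
        "partial": False,
    }
    root = config.seed

    def seed_for(stage: str) -> int:
        s = child_seed(root, stage)
        manifest["seeds"][stage] = s
        return s

    stage = "simulate"
    try:
        cohort_cfg = CohortConfig(
            n_patients=config.n_patients,
            sex_fraction_female=config.sex_fraction_female,
            seed=seed_for("cohort"),
        )
        cohort, genotypes = generate_cohort(cohort_cfg)
        catalog_cfg = DriverCatalogConfig(n_mutations=config.n_mutations)
        catalog, proteins = generate_driver_catalog(catalog_cfg, seed=seed_for("catalog"))
        _write(cohort, out / "cohort.tsv", index=False)
        write_genotypes(genotypes, out / "genotypes.tsv")
        cat_frame = pd.DataFrame([{
            "mutation_id": m.mutation_id, "gene": m.gene, "protein_id": m.protein_id,
            "kind": m.kind, "pos": m.position, "ref": m.ref, "alt": m.alt,
            "substitution_class": m.substitution_class, "signature": m.signature,
        } for m in catalog])
        _write(cat_frame, out / "catalog.tsv", index=False)
        with open(out / "proteins.fasta", "w") as fh:
            for pid_, seq in proteins.items():
                fh.write(f">{pid_}\n{seq}\n")
        manifest["stages"][stage] = {
            "n_patients": len(cohort), "n_mutations": len(catalog),
        }

        # allele-frequency control: male vs female genotype structure
        grouping = dict(zip(cohort["patient_id"], cohort["sex"]))
        freq_rows = {}
        for cls in ("I", "II"):
            freq = allele_frequencies(genotypes, grouping, cls)
            if {"male", "female"}.issubset(freq.columns):
                r = genotype_frequency_correlation(freq["male"].to_numpy(),
                                                  freq["female"].to_numpy())
            else:
                r = float("nan")
            freq_rows[cls] = r
        manifest["stages"]["genotype_frequency_correlation"] = freq_rows

        stage = "score"
        backend = SyntheticRankBackend(seed=seed_for("backend"))
        phbr_i = score_matrix(genotypes, catalog, proteins, backend, "I")
        phbr_ii = score_matrix(genotypes, catalog, proteins, backend, "II")
        _write(phbr_i, out / "phbr_I.tsv")
        _write(phbr_ii, out / "phbr_II.tsv")

        stage = "simulate_occurrence"
        occurrence = simulate_mutations(
            cohort, phbr_i, phbr_ii, config.truth,
            covariate=config.covariate, seed=seed_for("occurrence"),
        )
        expr_long, expressed = simulate_expression(occurrence, seed=seed_for("expression"))
        matrix = PHBRMatrix(phbr_i, phbr_ii, occurrence, expressed)
        long = matrix.to_long()
        _write(occurrence, out / "occurrence.tsv")
        _write(expr_long, out / "expression.tsv", index=False)
        _write(long, out / "phbr_long.tsv", index=False)
        manifest["stages"][stage] = {
            "n_occurrences": int(occurrence.to_numpy().sum()),
            "n_expressed": int((occurrence.to_numpy() * expressed.to_numpy()).sum()),
        }

        stage = "compare"
        sex_group = cohort.set_index("patient_id")["sex"]
        age_group = statsmod.age_categories(cohort.set_index("patient_id")["age_years"])
        sexage = (sex_group.map({"male": "M", "female": "F"}) + age_group.map(
            {"younger": "Y", "older": "O"})).dropna()
        comp_tables = {}
        for name, grouping_s, order in (
            ("sex", sex_group, ("female", "male")),
            ("age", age_group, ("younger", "older")),
            ("sex_age", sexage, None),
        ):
            for cls in ("I", "II"):
                comps = statsmod.compare_observed_scores(
                    long, grouping_s, cls, focal_order=order)
                comp_tables[f"{name}_{cls}"] = statsmod.comparisons_to_frame(comps)
        for key, frame in comp_tables.items():
            _write(frame, out / f"comparisons_{key}.tsv", index=False)

        stage = "permutation"
        perm_rows = []
        for cls, scores in (("I", phbr_i), ("II", phbr_ii)):
            res = statsmod.permutation_null(
                scores, occurrence, sex_group, focal="female", reference="male",
                n_perm=config.n_perm, seed=seed_for(f"perm_{cls}"),
            )
            perm_rows.append({"class": cls, **res.to_dict()})
        _write(pd.DataFrame(perm_rows), out / "permutation.tsv", index=False)

        stage = "models"
        fits, coef_table = glmm.fit_all_models(matrix, cohort, equations=config.equations)
        _write(coef_table, out / "model_coefficients.tsv", index=False)
        or_rows = []
        for eq, fit in fits.items():
            if isinstance(fit, Exception):
                manifest["stages"].setdefault("model_failures", {})[str(eq)] = repr(fit)
                continue
            design = glmm.build_design(matrix, cohort, glmm.ModelSpec(equation=eq))
            for score in ("phbr_i", "phbr_ii"):
                if score in fit.terms:
                    orr, (lo, hi) = glmm.quartile_odds_ratio(fit, score, design)
                    or_rows.append({"model": eq, "score": score, "odds_ratio": orr,
                                    "ci_low": lo, "ci_high": hi})
        _write(pd.DataFrame(or_rows), out / "quartile_odds_ratios.tsv", index=False)
        manifest["stages"][stage] = {
            "fitted": [eq for eq, f in fits.items() if not isinstance(f, Exception)],
            "truth": asdict(config.truth),
            "estimates": {
                str(eq): {t: f.coef(t) for t in ("intercept",) + f.terms}
                for eq, f in fits.items() if not isinstance(f, Exception)
            },
        }

        stage = "signatures"
        activities = simulate_signature_activities(
            cohort, sex_bias=config.signature_sex_bias, seed=seed_for("activities"))
        _write(activities, out / "signature_activities.tsv", index=False)
        ratios = sigmod.signature_sex_ratios(activities)
        _write(ratios, out / "signature_sex_ratios.tsv", index=False)
        fractions = sigmod.driver_signature_fractions([m.signature for m in catalog])
        _write(fractions.rename("percent").to_frame(), out / "driver_signature_fractions.tsv")
        # panel = every class I allele observed in the cohort, deduplicated
        panel = sorted(
            {mol.name: mol
             for gt in genotypes.values()
             for mol in assemble_molecules(gt, "I")}.values(),
            key=lambda m: m.name,
        )
        subcmp = sigmod.substitution_class_presentation(catalog, proteins, panel, backend, "I")
        _write(pd.DataFrame([subcmp.to_dict()]), out / "substitution_class_presentation.tsv",
               index=False)

        stage = "expression_model"
        if expr_long["expressed"].nunique() == 2 and min(
                np.bincount(expr_long["expressed"].astype(int))) >= 10:
            rows = expr_long.merge(cat_frame[["mutation_id", "gene"]], on="mutation_id")
            model, auroc = fit_expression_classifier(rows, seed=seed_for("expr_model"))
            model.save(out / "expression_model.json")
            manifest["stages"][stage] = {"mean_auroc": auroc}
        else:
            manifest["stages"][stage] = {"skipped": "insufficient class balance"}

    except Exception as exc:
        logger.exception("stage %s failed", stage)
        manifest["partial"] = True
        manifest["failed_stage"] = {"stage": stage, "error": repr(exc)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def validate_inputs(paths: Mapping[str, str], strict: bool = False) -> list[str]:
    """Schema and referential-integrity checks on an input file bundle.

    Recognized keys: cohort, genotypes, catalog, proteins (FASTA), ranks.
    Issues are returned as strings (and raised together when ``strict``).
    """
    issues: list[str] = []
    cohort = genos = catalog = proteins = None
    if "cohort" in paths:
        try:
            cohort = pd.read_csv(paths["cohort"], sep="\t")
            for col in ("patient_id", "sex", "age_years", "tumor_type"):
                if col not in cohort.columns:
                    issues.append(f"cohort: missing column {col}")
        except Exception as exc:
            issues.append(f"cohort: unreadable ({exc})")
    if "genotypes" in paths:
        try:
            genos = pd.read_csv(paths["genotypes"], sep="\t")
            for col in ("patient_id", "gene", "allele"):
                if col not in genos.columns:
                    issues.append(f"genotypes: missing column {col}")
            if cohort is not None and genos is not None and "patient_id" in genos.columns:
                unknown = set(genos["patient_id"]) - set(cohort.get("patient_id", []))
                if unknown:
                    issues.append(f"genotypes: {len(unknown)} unknown patient_id(s), "
                                  f"e.g. {sorted(unknown)[:3]}")
        except Exception as exc:
            issues.append(f"genotypes: unreadable ({exc})")
    if "proteins" in paths:
        try:
            from Bio import SeqIO

            proteins = {rec.id: str(rec.seq)
                        for rec in SeqIO.parse(str(paths["proteins"]), "fasta")}
        except Exception as exc:
            issues.append(f"proteins: unreadable ({exc})")
    if "catalog" in paths:
        try:
            catalog = pd.read_csv(paths["catalog"], sep="\t", keep_default_na=False)
            for col in ("mutation_id", "protein_id", "kind", "pos", "ref", "alt"):
                if col not in catalog.columns:
                    issues.append(f"catalog: missing column {col}")
            if proteins is not None and "protein_id" in getattr(catalog, "columns", []):
                for _, row in catalog.iterrows():
                    seq = proteins.get(row["protein_id"])
                    if seq is None:
                        issues.append(f"catalog: {row['mutation_id']} references missing "
                                      f"protein {row['protein_id']}")
                    elif row["kind"] == "missense":
                        pos = int(row["pos"])
                        if pos > len(seq) or seq[pos - 1] != row["ref"]:
                            found = seq[pos - 1] if pos <= len(seq) else "<end>"
                            issues.append(
                                f"catalog: {row['mutation_id']} ref mismatch at position "
                                f"{pos} (expected {row['ref']}, found {found})")
        except Exception as exc:
            issues.append(f"catalog: unreadable ({exc})")
    if strict and issues:
        raise ValueError("input validation failed:\n" + "\n".join(issues))
    return issues
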