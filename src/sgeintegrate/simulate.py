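"""Synthetic multi-assay saturation-genome-editing (SGE) screens.

Generates variant tables, per-replicate raw functional scores and ground
truth with the statistical structure the integrated models assume: a
two-component mixture of latent variant effects (functional vs
non-functional, lower score = depleted = non-functional), replicate-by-exon
location and scale batch effects, heavy-tailed t-distributed residual noise,
two assays with unequal replicate counts, and an affine distortion of the
second assay's scale. Silent (synonymous) variants are always functional and
nonsense variants always non-functional, mirroring their use as assay
controls; canonical-splice variants are treated as loss-of-function. The
pathogenic fraction among missense variants defaults to 0.227.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONSEQUENCES = ("synonymous", "nonsense", "missense", "canonical_splice")

_BASES = np.array(list("ACGT"))

VARIANT_COLUMNS = [
    "variant_id", "chrom", "pos", "ref", "alt", "exon", "consequence",
    "bayesdel", "spliceai_flag", "faf", "preassigned_codes",
    "clinvar_standard", "hdr_standard",
]
SCORE_COLUMNS = ["variant_id", "assay", "replicate", "exon", "raw_score"]
TRUTH_COLUMNS = ["variant_id", "true_status", "true_effect"]


def _default_mix() -> dict[str, float]:
    return {
        "synonymous": 0.18,
        "nonsense": 0.07,
        "missense": 0.70,
        "canonical_splice": 0.05,
    }


def _default_replicates() -> dict[str, int]:
    # A1 ~ haploid-cell screen (>=3 replicates), A2 ~ ES-cell screen (2).
    return {"A1": 3, "A2": 2}


def _default_exons() -> list[str]:
    # BRCA2 DNA-binding domain spans exons 15-26.
    return [f"exon{i}" for i in range(15, 27)]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic SGE screen generator.

    Scores are on an arbitrary log-depletion-like scale where lower values
    mean stronger depletion (loss of function). Defaults separate the two
    mixture components by 8 component SDs so control-driven calibration is
    unambiguous; stress tests may narrow the gap.
    """

    n_variants: int = 500
    exon_ids: list[str] = field(default_factory=_default_exons)
    replicates_per_assay: dict[str, int] = field(default_factory=_default_replicates)
    frac_missense_pathogenic: float = 0.227
    consequence_mix: dict[str, float] = field(default_factory=_default_mix)
    mu_functional: float = 0.0
    mu_nonfunctional: float = -1.2
    sigma_functional: float = 0.15
    sigma_nonfunctional: float = 0.15
    batch_location_sd: float = 0.05
    batch_logscale_sd: float = 0.05
    t_df: float = 6.0
    residual_scale: float = 0.1
    assay_offset: float = 0.5
    assay_scale: float = 1.3
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_variants < 0:
            raise ValueError("n_variants must be non-negative")
        mix_total = sum(self.consequence_mix.values())
        if abs(mix_total - 1.0) > 1e-9:
            raise ValueError(f"consequence_mix must sum to 1, got {mix_total}")
        if set(self.consequence_mix) - set(CONSEQUENCES):
            raise ValueError("unknown consequence class in consequence_mix")
        for name in ("sigma_functional", "sigma_nonfunctional", "residual_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("batch_location_sd", "batch_logscale_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.t_df <= 2:
            raise ValueError("t_df must be > 2 for a finite variance")
        if any(r < 1 for r in self.replicates_per_assay.values()):
            raise ValueError("replicate counts must be >= 1")
        if not 0.0 <= self.frac_missense_pathogenic <= 1.0:
            raise ValueError("frac_missense_pathogenic must be a probability")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not self.exon_ids:
            raise ValueError("exon_ids must be non-empty")
        if self.assay_scale <= 0:
            raise ValueError("assay_scale must be positive (direction-preserving)")


def _annotate(rng, consequence, status):
    """Draw annotation columns consistent with ground truth.

    BayesDel-like scores are drawn high for non-functional and low for
    functional variants; population frequency (FAF) is mostly absent for
    non-functional variants (rare, hence PM2-eligible) and present for a
    minority of functional ones.
    """
    n = len(consequence)
    nonfunc = status == "nonfunctional"
    bayesdel = np.where(
        nonfunc,
        rng.normal(0.55, 0.08, n),
        rng.normal(0.02, 0.06, n),
    ).clip(-1.3, 1.0)
    spliceai_flag = consequence == "canonical_splice"

    faf = np.full(n, np.nan)
    has_faf_func = (~nonfunc) & (rng.random(n) < 0.30)
    faf[has_faf_func] = 10 ** rng.uniform(-5.0, -2.5, has_faf_func.sum())
    has_faf_nonfunc = nonfunc & (rng.random(n) < 0.02)
    faf[has_faf_nonfunc] = rng.uniform(1e-6, 2e-5, has_faf_nonfunc.sum())

    preassigned = np.where(
        np.isin(consequence, ["nonsense", "canonical_splice"]),
        "PVS1:very_strong",
        "",
    )

    missense = consequence == "missense"
    clinvar = np.full(n, "none", dtype=object)
    clinvar[missense & nonfunc & (rng.random(n) < 0.20)] = "P/LP"
    clinvar[missense & ~nonfunc & (rng.random(n) < 0.05)] = "B/LB"
    hdr = np.full(n, "none", dtype=object)
    hdr[missense & nonfunc & (rng.random(n) < 0.30)] = "abnormal"
    hdr[missense & ~nonfunc & (rng.random(n) < 0.10)] = "normal"
    return bayesdel, spliceai_flag, faf, preassigned, clinvar, hdr


def simulate_screen(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a two-assay SGE screen with known ground truth.

    Returns
    -------
    variants, scores, truth : DataFrame
        ``variants`` one row per SNV with annotations and (sparse) clinical/
        functional standards; ``scores`` one row per (variant, assay,
        replicate) raw observation, already reflecting batch effects, t noise
        and the second assay's affine distortion; ``truth`` the latent status
        and effect of each variant. Fully reproducible given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_variants

    classes = list(config.consequence_mix)
    probs = np.array([config.consequence_mix[c] for c in classes])
    consequence = rng.choice(classes, size=n, p=probs)
    for cls in ("synonymous", "nonsense"):
        if cls in config.consequence_mix and not np.any(consequence == cls):
            warnings.warn(
                f"no {cls} variants drawn; downstream control calibration "
                "will fail",
                stacklevel=2,
            )

    status = np.where(
        consequence == "synonymous",
        "functional",
        np.where(
            np.isin(consequence, ["nonsense", "canonical_splice"]),
            "nonfunctional",
            np.where(
                rng.random(n) < config.frac_missense_pathogenic,
                "nonfunctional",
                "functional",
            ),
        ),
    )

    nonfunc = status == "nonfunctional"
    theta = np.where(
        nonfunc,
        rng.normal(config.mu_nonfunctional, config.sigma_nonfunctional, n),
        rng.normal(config.mu_functional, config.sigma_functional, n),
    )

    exon = rng.choice(config.exon_ids, size=n)
    variant_id = np.array([f"v{i:05d}" for i in range(n)])
    ref = rng.choice(_BASES, size=n)
    alt = np.array([rng.choice(_BASES[_BASES != r]) for r in ref])

    bayesdel, spliceai_flag, faf, preassigned, clinvar, hdr = _annotate(
        rng, consequence, status
    )
    variants = pd.DataFrame(
        {
            "variant_id": variant_id,
            "chrom": "13",
            "pos": 32356461 + np.arange(n),
            "ref": ref,
            "alt": alt,
            "exon": exon,
            "consequence": consequence,
            "bayesdel": np.round(bayesdel, 4),
            "spliceai_flag": spliceai_flag,
            "faf": faf,
            "preassigned_codes": preassigned,
            "clinvar_standard": clinvar,
            "hdr_standard": hdr,
        }
    )

    # Replicate-by-exon batch effects, drawn per (assay, replicate, exon).
    batch_b: dict[tuple[str, int, str], float] = {}
    batch_g: dict[tuple[str, int, str], float] = {}
    for assay in sorted(config.replicates_per_assay):
        for rep in range(1, config.replicates_per_assay[assay] + 1):
            for ex in config.exon_ids:
                batch_b[(assay, rep, ex)] = rng.normal(0, config.batch_location_sd)
                batch_g[(assay, rep, ex)] = rng.normal(0, config.batch_logscale_sd)

    rows = []
    for assay in sorted(config.replicates_per_assay):
        n_rep = config.replicates_per_assay[assay]
        for rep in range(1, n_rep + 1):
            b = np.array([batch_b[(assay, rep, e)] for e in exon])
            g = np.array([batch_g[(assay, rep, e)] for e in exon])
            eps = config.residual_scale * rng.standard_t(config.t_df, size=n)
            y = b + np.exp(g) * theta + eps
            if assay != "A1":
                y = config.assay_offset + config.assay_scale * y
            keep = rng.random(n) >= config.missing_rate
            rows.append(
                pd.DataFrame(
                    {
                        "variant_id": variant_id[keep],
                        "assay": assay,
                        "replicate": rep,
                        "exon": exon[keep],
                        "raw_score": y[keep],
                    }
                )
            )
    scores = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=SCORE_COLUMNS
    )
    scores = scores.sort_values(
        ["variant_id", "assay", "replicate"], kind="stable"
    ).reset_index(drop=True)

    truth = pd.DataFrame(
        {"variant_id": variant_id, "true_status": status, "true_effect": theta}
    )
    return variants, scores, truth


def write_fixture(dir_path, variants, scores, truth) -> dict[str, str]:
    """Write variants.tsv / scores.tsv / truth.tsv into ``dir_path``."""
    from . import io

    return io.write_screen(dir_path, variants, scores, truth)
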