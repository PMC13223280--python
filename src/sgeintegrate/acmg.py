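"""Points-based ClinGen/ACMG/AMP classification engine.

Evidence codes carry integer point weights by strength and polarity:
pathogenic very strong +8, strong +4, moderate +2, supporting +1; benign
stand-alone -8, strong -4, moderate -2, supporting -1. Totals map to the
final class: P at >= +10, LP at +6..+9, VUS at -1..+5, LB at -6..-2, B at
<= -7.

Derived here: the functional code (PS3/BS3, strength modulated by the
integrated model's evidence category and structurally capped at +/-4), the
population-frequency code (BA1/BS1/BS1_Supporting from the filter allele
frequency, PM2_Supporting for variants absent from the population), and
the in-silico code (PP3 from BayesDel or a splice-prediction flag, BP4
below a configurable benign BayesDel cutoff). All other codes (PVS1, PS1,
PM3, PM5, PP4, BP5, BS2, BP7, ...) require external data and are consumed
as pre-assigned ``CODE:strength`` inputs.

Variants whose functional call contradicts a ClinVar or HDR standard are
designated VUS_discordant regardless of points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categories import category_side

logger = logging.getLogger(__name__)

PATHOGENIC_POINTS = {"very_strong": 8, "strong": 4, "moderate": 2,
                     "supporting": 1}
BENIGN_POINTS = {"stand_alone": -8, "strong": -4, "moderate": -2,
                 "supporting": -1}

#: BayesDel cutoff below which BP4 applies. Externally sourced expert-panel
#: convention; this threshold is not derived from the assay data.
BP4_BAYESDEL_CUTOFF = 0.15
PP3_BAYESDEL_CUTOFF = 0.3
BA1_FAF = 0.001
BS1_FAF = 0.0001
BS1_SUPPORTING_FAF = 0.00002

#: Families whose members are mutually exclusive within one profile.
_EXCLUSIVE_FAMILIES = {
    "functional": ("PS3", "BS3"),
    "frequency": ("BA1", "BS1", "BS1_Supporting", "PM2_Supporting"),
    "insilico": ("PP3", "BP4"),
}

CLASS_BANDS = (
    ("P", 10, None),
    ("LP", 6, 9),
    ("VUS", -1, 5),
    ("LB", -6, -2),
    ("B", None, -7),
)


@dataclass(frozen=True)
class EvidenceCode:
    code: str
    strength: str
    source: str = "derived"

    @property
    def pathogenic(self) -> bool:
        return self.code[0] == "P"

    @property
    def points(self) -> int:
        table = PATHOGENIC_POINTS if self.pathogenic else BENIGN_POINTS
        if self.strength not in table:
            raise ValueError(
                f"{self.code}: strength {self.strength!r} invalid for a "
                f"{'pathogenic' if self.pathogenic else 'benign'} code"
            )
        return table[self.strength]


@dataclass
class EvidenceProfile:
    variant_id: str
    codes: list

    @property
    def total_points(self) -> int:
        return sum(c.points for c in self.codes)

    def validate(self) -> None:
        names = [c.code for c in self.codes]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"{self.variant_id}: duplicate codes {dup}")
        for family, members in _EXCLUSIVE_FAMILIES.items():
            present = [n for n in names
                       if n in members or n.split("_")[0] in members]
            if len(present) > 1:
                raise ValueError(
                    f"{self.variant_id}: mutually exclusive {family} codes "
                    f"applied together: {present}"
                )


def functional_evidence(category: str) -> EvidenceCode | None:
    """PS3/BS3 with strength set by the seven-level functional category.

    The +/-4 cap is structural: the strongest strength ever assigned is
    'strong', never 'very_strong'/'stand_alone'.
    """
    mapping = {
        "P_Strong": ("PS3", "strong"),
        "P_Moderate": ("PS3", "moderate"),
        "P_Supporting": ("PS3", "supporting"),
        "B_Supporting": ("BS3", "supporting"),
        "B_Moderate": ("BS3", "moderate"),
        "B_Strong": ("BS3", "strong"),
        "Uncertain": None,
    }
    if category not in mapping:
        raise ValueError(f"unknown functional category {category!r}")
    hit = mapping[category]
    return EvidenceCode(*hit) if hit else None


def frequency_evidence(faf) -> EvidenceCode | None:
    """BA1/BS1/BS1_Supporting from the filter allele frequency; absence
    from the population yields PM2_Supporting."""
    if faf is None or (isinstance(faf, float) and np.isnan(faf)):
        return EvidenceCode("PM2_Supporting", "supporting")
    if not 0.0 <= faf <= 1.0:
        raise ValueError(f"faf must lie in [0, 1], got {faf}")
    if faf > BA1_FAF:
        return EvidenceCode("BA1", "stand_alone")
    if faf > BS1_FAF:
        return EvidenceCode("BS1", "strong")
    if faf > BS1_SUPPORTING_FAF:
        return EvidenceCode("BS1_Supporting", "supporting")
    return None


def insilico_evidence(bayesdel, spliceai_flag: bool,
                      bp4_cutoff: float = BP4_BAYESDEL_CUTOFF
                      ) -> EvidenceCode | None:
    """PP3 (moderate for high BayesDel, supporting for splice-prediction
    hits) or BP4 below the benign BayesDel cutoff."""
    has_bd = bayesdel is not None and not (
        isinstance(bayesdel, float) and np.isnan(bayesdel))
    if has_bd and bayesdel >= PP3_BAYESDEL_CUTOFF:
        return EvidenceCode("PP3", "moderate")
    if spliceai_flag:
        return EvidenceCode("PP3", "supporting")
    if has_bd and bayesdel <= bp4_cutoff:
        return EvidenceCode("BP4", "supporting")
    return None


def parse_preassigned(spec: str) -> list[EvidenceCode]:
    """Parse a semicolon-separated ``CODE:strength`` list."""
    codes = []
    for token in str(spec or "").split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            code, strength = token.split(":")
        except ValueError as exc:
            raise ValueError(f"malformed preassigned code {token!r}") from exc
        codes.append(EvidenceCode(code.strip(), strength.strip(),
                                  source="preassigned"))
    return codes


def points_to_class(total: int) -> str:
    for name, lo, hi in CLASS_BANDS:
        if (lo is None or total >= lo) and (hi is None or total <= hi):
            return name
    raise AssertionError("point bands must partition the integers")


def _standard_conflicts(call_side: str, clinvar: str, hdr: str) -> bool:
    if call_side == "P":
        return clinvar == "B/LB" or hdr == "normal"
    if call_side == "B":
        return clinvar == "P/LP" or hdr == "abnormal"
    return False


def classify(profile: EvidenceProfile, call_category: str | None = None,
             clinvar_standard: str = "none",
             hdr_standard: str = "none") -> dict:
    """Final class from an evidence profile, with the discordance override.

    If ``call_category`` sits on the opposite side of a ClinVar or HDR
    standard for the same variant, the class becomes ``VUS_discordant``
    regardless of points.
    """
    profile.validate()
    total = profile.total_points
    cls = points_to_class(total)
    if call_category is not None and call_category != "Uncertain":
        side = category_side(call_category)
        if _standard_conflicts(side, clinvar_standard, hdr_standard):
            cls = "VUS_discordant"
    return {
        "variant_id": profile.variant_id,
        "class": cls,
        "total_points": total,
        "codes": [f"{c.code}:{c.strength}" for c in profile.codes],
    }


def build_profile(variant: pd.Series, category: str | None,
                  bp4_cutoff: float = BP4_BAYESDEL_CUTOFF) -> EvidenceProfile:
    """Assemble derived + preassigned codes for one variant row."""
    codes = list(parse_preassigned(variant.get("preassigned_codes", "")))
    preassigned_names = {c.code.split("_")[0] for c in codes}
    if category is not None:
        c = functional_evidence(category)
        if c is not None:
            codes.append(c)
    if not {"BA1", "BS1", "PM2"} & preassigned_names:
        c = frequency_evidence(variant.get("faf"))
        if c is not None:
            codes.append(c)
    if not {"PP3", "BP4"} & preassigned_names:
        c = insilico_evidence(variant.get("bayesdel"),
                              bool(variant.get("spliceai_flag", False)),
                              bp4_cutoff)
        if c is not None:
            codes.append(c)
    return EvidenceProfile(variant_id=variant["variant_id"], codes=codes)


def run_classification(variants: pd.DataFrame, calls: pd.DataFrame,
                       bp4_cutoff: float = BP4_BAYESDEL_CUTOFF):
    """Classify every variant with and without functional evidence.

    Returns the per-variant table and summary counts. VUS_discordant counts
    as VUS in the classified-fraction summary.
    """
    call_map = calls.set_index("variant_id")["category"].to_dict()
    rows = []
    for _, var in variants.iterrows():
        vid = var["variant_id"]
        category = call_map.get(vid)
        if category is None:
            logger.info("no functional call for %s; classified without "
                        "functional evidence", vid)
        with_f = classify(
            build_profile(var, category, bp4_cutoff),
            call_category=category,
            clinvar_standard=var.get("clinvar_standard", "none"),
            hdr_standard=var.get("hdr_standard", "none"),
        )
        without_f = classify(build_profile(var, None, bp4_cutoff))
        rows.append({
            "variant_id": vid,
            "class_with_functional": with_f["class"],
            "class_without_functional": without_f["class"],
            "points_with": with_f["total_points"],
            "points_without": without_f["total_points"],
            "codes_applied": ";".join(with_f["codes"]),
        })
    table = pd.DataFrame(rows)

    def _summary(col: str) -> dict:
        counts = table[col].value_counts().to_dict()
        classified = sum(counts.get(k, 0) for k in ("P", "LP", "LB", "B"))
        return {
            "counts": {k: int(v) for k, v in counts.items()},
            "n_classified": int(classified),
            "classified_fraction": (classified / len(table)
                                    if len(table) else float("nan")),
        }

    summary = {
        "with_functional": _summary("class_with_functional"),
        "without_functional": _summary("class_without_functional"),
        "n_variants": int(len(table)),
    }
    return table, summary
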