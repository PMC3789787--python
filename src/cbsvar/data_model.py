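"""Typed representation of the CBS variant panel.

The panel describes single amino-acid substitutions in human cystathionine
beta-synthase (CBS, reference protein NP_000062) assayed by functional
complementation of yeast *cys4* null strains.  Each variant carries a
Rosetta-predicted folding free-energy change (ddG, kcal/mol, missing for
residues outside the solved structure), a three-way phenotype category
(nonfunctional / sensitive / benign), and relative growth rates measured
under titrated pyridoxine (vitamin B6) and, for the *hem1*-deleted assay,
delta-aminolevulinate (heme precursor) supplementation.

Two bundled fixtures transcribe the published panel: the 58-variant
pyridoxine-titration table and the 9-variant dual-cofactor (hem1-delta)
table.  ``load_table1``/``load_table2`` return validated panels.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "Category",
    "SigFlag",
    "Construction",
    "Substitution",
    "AssayCondition",
    "GrowthResult",
    "VariantRecord",
    "VariantPanel",
    "parse_substitution",
    "load_table1",
    "load_table2",
    "validate_panel",
    "write_panel",
    "read_panel",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

REFERENCE_PROTEIN = "NP_000062"
REFERENCE_MRNA = "NM_000071"

#: pyridoxine doses (ng/mL) of the HEM1 titration series, high to low
TABLE1_DOSES = (400.0, 4.0, 2.0, 1.0)


class Category(str, Enum):
    """Three-way growth phenotype of a variant."""

    NONFUNCTIONAL = "nonfunctional"
    SENSITIVE = "sensitive"
    BENIGN = "benign"


class SigFlag(str, Enum):
    """Significance of the variant-vs-major-allele rate difference."""

    NONE = "none"    # not significant
    P01 = "p01"      # P < 0.01  (printed as a single asterisk)
    P001 = "p001"    # P < 0.001 (printed as a double asterisk)


class Construction(str, Enum):
    """How the variant was made: site-directed or random mutagenesis."""

    DIRECTED = "directed"
    RANDOM = "random"
    UNKNOWN = "unknown"


class SubstitutionParseError(ValueError):
    pass


class PanelLoadError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class Substitution:
    """One amino-acid substitution, e.g. I278T, on NP_000062 numbering."""

    wt_aa: str
    position: int
    mut_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa not in AMINO_ACIDS or self.mut_aa not in AMINO_ACIDS:
            raise SubstitutionParseError(
                f"non-canonical amino acid in {self.wt_aa}{self.position}{self.mut_aa}"
            )
        if self.wt_aa == self.mut_aa:
            raise SubstitutionParseError(
                f"silent substitution {self.wt_aa}{self.position}{self.mut_aa}"
            )
        if self.position < 1:
            raise SubstitutionParseError(f"position must be >= 1, got {self.position}")

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


_SUB_RE = re.compile(r"^([A-Za-z]{1,3})(\d+)([A-Za-z]{1,3})$")


def _to_one_letter(code: str, token: str) -> str:
    code = code.upper()
    if len(code) == 1:
        return code
    if len(code) == 3 and code in _THREE_TO_ONE:
        return _THREE_TO_ONE[code]
    raise SubstitutionParseError(f"unrecognized amino-acid code {code!r} in {token!r}")


def parse_substitution(token: str) -> Substitution:
    """Parse a substitution token like ``"I278T"`` or ``"Ile278Thr"``.

    Raises :class:`SubstitutionParseError` for malformed tokens,
    non-canonical residue codes, or silent (wt == mut) substitutions.
    """
    m = _SUB_RE.match(token.strip())
    if not m:
        raise SubstitutionParseError(f"malformed substitution token {token!r}")
    wt, pos, mut = m.groups()
    return Substitution(_to_one_letter(wt, token), int(pos), _to_one_letter(mut, token))


@dataclass(frozen=True)
class AssayCondition:
    """One growth medium: pyridoxine dose and, in hem1-delta strains,
    the delta-aminolevulinate (d-ALA) dose that sets heme availability."""

    pyridoxine: float                 # ng/mL
    dala: float | None = None         # ug/mL; present iff hem1_deleted
    hem1_deleted: bool = False

    def __post_init__(self) -> None:
        if (self.dala is not None) != self.hem1_deleted:
            raise ValueError("dala dose must be present iff the strain is hem1-deleted")
        if self.pyridoxine < 0 or (self.dala is not None and self.dala < 0):
            raise ValueError("doses must be non-negative")

    def label(self) -> str:
        if self.hem1_deleted:
            return f"B6={self.pyridoxine:g}ng/mL,dALA={self.dala:g}ug/mL"
        return f"B6={self.pyridoxine:g}ng/mL"


@dataclass(frozen=True)
class GrowthResult:
    """Relative growth rate (variant / major allele) in one condition.

    ``relative_rate`` is None when no rate was determinable — either the
    variant did not grow (nonfunctional) or the measurement was not made
    (printed "n/d"); the record's category distinguishes the two.
    """

    condition: AssayCondition
    relative_rate: float | None = None
    sd: float | None = None
    sig_flag: SigFlag = SigFlag.NONE
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.relative_rate is not None and self.relative_rate < 0:
            raise ValueError("relative_rate must be >= 0")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.sig_flag is not SigFlag.NONE and self.relative_rate is None:
            raise ValueError("significance flag requires a measured rate")


@dataclass(frozen=True)
class VariantRecord:
    """One CBS variant: identity, predicted ddG, category, growth results."""

    plasmid_id: str
    nt_change: str
    substitution: Substitution
    ddg: float | None           # kcal/mol, Rosetta scale; None = outside structure
    category: Category
    results: tuple[GrowthResult, ...] = ()
    construction: Construction = Construction.UNKNOWN

    def result_at(self, condition: AssayCondition) -> GrowthResult:
        for r in self.results:
            if r.condition == condition:
                return r
        raise KeyError(
            f"{self.substitution}: no result at {condition.label()}"
        )


@dataclass(frozen=True)
class VariantPanel:
    """A collection of variant records sharing a reference sequence."""

    records: tuple[VariantRecord, ...]
    reference_protein: str = REFERENCE_PROTEIN
    reference_mrna: str = REFERENCE_MRNA

    def __iter__(self) -> Iterable[VariantRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, token: str) -> VariantRecord:
        sub = parse_substitution(token)
        for rec in self.records:
            if rec.substitution == sub:
                return rec
        raise KeyError(token)

    def category_counts(self) -> dict[Category, int]:
        counts = {c: 0 for c in Category}
        for rec in self.records:
            counts[rec.category] += 1
        return counts

    def with_ddg(self) -> "VariantPanel":
        return replace(self, records=tuple(r for r in self.records if r.ddg is not None))


# ---------------------------------------------------------------------------
# fixture loading

def _default_fixture(name: str) -> Path:
    return Path(str(resources.files("cbsvar").joinpath("data", name)))


def _parse_rate_cell(rate: object, sd: object, flag: object, category: Category,
                     condition: AssayCondition, row_id: str) -> GrowthResult:
    rate_s = "" if rate is None or (isinstance(rate, float) and math.isnan(rate)) else str(rate).strip()
    sd_s = "" if sd is None or (isinstance(sd, float) and math.isnan(sd)) else str(sd).strip()
    flag_s = "" if flag is None or (isinstance(flag, float) and math.isnan(flag)) else str(flag).strip()

    sig = {"": SigFlag.NONE, "*": SigFlag.P01, "**": SigFlag.P001}.get(flag_s)
    if sig is None:
        raise PanelLoadError(f"{row_id}: unrecognized significance flag {flag_s!r}")

    if rate_s in ("", "n/d"):
        return GrowthResult(condition=condition, sig_flag=SigFlag.NONE)
    value = float(rate_s)
    if value == 0.0 and category is Category.NONFUNCTIONAL:
        # the printed 0 for a no-growth variant: no determinable rate
        return GrowthResult(condition=condition, sig_flag=SigFlag.NONE)
    return GrowthResult(
        condition=condition,
        relative_rate=value,
        sd=float(sd_s) if sd_s else None,
        sig_flag=sig,
    )


def load_table1(path: str | Path | None = None) -> VariantPanel:
    """Load the 58-variant pyridoxine-titration panel (bundled by default)."""
    path = _default_fixture("table1.tsv") if path is None else Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        row_id = f"{path.name}:{row['plasmid_id']}"
        try:
            sub = parse_substitution(row["substitution"])
            category = Category(row["category"])
            ddg = float(row["ddg"]) if row["ddg"].strip() else None
            results = []
            for dose in TABLE1_DOSES:
                key = f"{dose:g}"
                cond = AssayCondition(pyridoxine=dose)
                results.append(_parse_rate_cell(
                    row[f"rate_{key}"], row[f"sd_{key}"], row[f"flag_{key}"],
                    category, cond, row_id))
            rec = VariantRecord(
                plasmid_id=row["plasmid_id"],
                nt_change=row["nt_change"].replace("→", ">"),
                substitution=sub,
                ddg=ddg,
                category=category,
                results=tuple(results),
            )
        except (ValueError, KeyError) as exc:
            raise PanelLoadError(f"{row_id}: {exc}") from exc
        records.append(rec)
    panel = VariantPanel(records=tuple(records))
    violations = validate_panel(panel)
    if violations:
        raise PanelLoadError("; ".join(violations))
    return panel


def load_table2(path: str | Path | None = None) -> VariantPanel:
    """Load the 9-variant hem1-delta dual-cofactor panel (bundled by default)."""
    path = _default_fixture("table2.tsv") if path is None else Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    by_sub: dict[str, list[GrowthResult]] = {}
    order: list[str] = []
    for _, row in df.iterrows():
        token = row["substitution"]
        row_id = f"{path.name}:{token}"
        try:
            cond = AssayCondition(
                pyridoxine=float(row["pyridoxine_ng_ml"]),
                dala=float(row["dala_ug_ml"]),
                hem1_deleted=True,
            )
            rate_s = row["rate"].strip()
            if rate_s in ("", "n/d"):
                res = GrowthResult(condition=cond)
            else:
                sd_s = row["sd"].strip()
                res = GrowthResult(
                    condition=cond,
                    relative_rate=float(rate_s),
                    sd=float(sd_s) if sd_s else None,
                )
        except ValueError as exc:
            raise PanelLoadError(f"{row_id}: {exc}") from exc
        if token not in by_sub:
            order.append(token)
        by_sub.setdefault(token, []).append(res)

    records = []
    for i, token in enumerate(order):
        results = by_sub[token]
        if len(results) != 4:
            raise PanelLoadError(f"{token}: expected 4 conditions, got {len(results)}")
        # every variant in the dual-cofactor panel is B6-sensitive
        records.append(VariantRecord(
            plasmid_id=f"t2-{i:02d}",
            nt_change="",
            substitution=parse_substitution(token),
            ddg=None,
            category=Category.SENSITIVE,
            results=tuple(results),
        ))
    return VariantPanel(records=tuple(records))


# ---------------------------------------------------------------------------
# validation

def _codon_consistent(nt_change: str, position: int) -> bool:
    """First mutated nucleotide must fall within +/-2 nt of the codon."""
    m = re.match(r"^\s*(\d+)", nt_change)
    if not m:
        return False
    nt = int(m.group(1))
    codon_start = (position - 1) * 3 + 1
    return codon_start - 2 <= nt <= codon_start + 4


def validate_panel(panel: VariantPanel) -> list[str]:
    """Return human-readable descriptions of every invariant violation.

    An empty list means the panel is internally consistent. Violations are
    data, not exceptions, so callers can report them all at once.
    """
    violations: list[str] = []
    seen_plasmids: set[str] = set()
    seen_subs: set[Substitution] = set()
    for rec in panel.records:
        rid = f"{rec.plasmid_id} ({rec.substitution})"
        if rec.plasmid_id in seen_plasmids:
            violations.append(f"{rid}: duplicate plasmid_id")
        seen_plasmids.add(rec.plasmid_id)
        if rec.substitution in seen_subs:
            violations.append(f"{rid}: duplicate substitution")
        seen_subs.add(rec.substitution)
        if rec.category is Category.NONFUNCTIONAL:
            if any(r.relative_rate is not None for r in rec.results):
                violations.append(f"{rid}: nonfunctional record carries a growth rate")
        if rec.nt_change and not _codon_consistent(rec.nt_change, rec.substitution.position):
            violations.append(
                f"{rid}: nucleotide change {rec.nt_change!r} inconsistent with "
                f"residue {rec.substitution.position}"
            )
    return violations


# ---------------------------------------------------------------------------
# round-trip serialization (the fixture TSV dialect)

def write_panel(panel: VariantPanel, path: str | Path) -> None:
    """Serialize a HEM1-series panel in the bundled table dialect."""
    rows = []
    for rec in panel.records:
        row: dict[str, str] = {
            "plasmid_id": rec.plasmid_id,
            "nt_change": rec.nt_change,
            "substitution": str(rec.substitution),
            "ddg": "" if rec.ddg is None else f"{rec.ddg:g}",
            "category": rec.category.value,
        }
        for res in rec.results:
            key = f"{res.condition.pyridoxine:g}"
            if res.relative_rate is None:
                row[f"rate_{key}"] = "0" if rec.category is Category.NONFUNCTIONAL else "n/d"
                row[f"sd_{key}"] = ""
                row[f"flag_{key}"] = ""
            else:
                row[f"rate_{key}"] = f"{res.relative_rate:.2f}"
                row[f"sd_{key}"] = "" if res.sd is None else f"{res.sd:.2f}"
                row[f"flag_{key}"] = {SigFlag.NONE: "", SigFlag.P01: "*", SigFlag.P001: "**"}[res.sig_flag]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> VariantPanel:
    """Inverse of :func:`write_panel` (same contract as ``load_table1``)."""
    return load_table1(path)
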