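"""Clinical code lists: named, category-tagged sets of coded-record codes.

The ascertainment algorithm is driven entirely by which category a clinical
code belongs to (lung cancer, small cell cancer, symptom, diagnostic
procedure, terminal care, comorbidity, lifestyle).  Real UK databases use
Read codes; the bundled defaults use transparent synthetic identifiers with
the same role.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["CodeList", "load_codelist", "save_codelist", "default_codelists"]

KNOWN_CATEGORIES = (
    "lung_cancer",
    "scc",
    "symptom",
    "procedure",
    "terminal_care",
    "comorbidity",
    "lifestyle",
    "encounter",
)


@dataclass
class CodeList:
    """Mapping from category tag to a set of clinical codes.

    A code may appear in only one category; the lung-cancer and SCC lists
    in particular must be disjoint for group assignment to be well defined.
    """

    categories: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for cat, codes in self.categories.items():
            if cat not in KNOWN_CATEGORIES:
                raise ValueError(f"unknown code category {cat!r}")
            for code in codes:
                if code in seen:
                    raise ValueError(
                        f"code {code!r} tagged with two categories: "
                        f"{seen[code]!r} and {cat!r}"
                    )
                seen[code] = cat

    def __getitem__(self, category: str) -> set[str]:
        return self.categories.get(category, set())

    @property
    def lung_cancer(self) -> set[str]:
        return self["lung_cancer"]

    @property
    def scc(self) -> set[str]:
        return self["scc"]

    @property
    def cancer(self) -> set[str]:
        """Union of lung-cancer and SCC codes (any qualifying index code)."""
        return self.lung_cancer | self.scc

    def category_of(self, code: str) -> str | None:
        for cat, codes in self.categories.items():
            if code in codes:
                return cat
        return None


def default_codelists() -> CodeList:
    """Synthetic code dictionary used by the generator and the examples."""
    return CodeList(
        {
            "lung_cancer": {"LUNG_CA_1", "LUNG_CA_2", "LUNG_CA_3"},
            "scc": {"SCC_1", "SCC_2"},
            "symptom": {
                "SYMP_COUGH",
                "SYMP_HAEMOPTYSIS",
                "SYMP_CHEST_PAIN",
                "SYMP_DYSPNOEA",
                "SYMP_WEIGHT_LOSS",
                "SYMP_CHEST_INFECTION",
            },
            "procedure": {"PROC_CXR", "PROC_CT", "PROC_BRONCH", "PROC_BIOPSY"},
            "terminal_care": {"TERM_CARE"},
            "comorbidity": {
                "COM_MI",
                "COM_STROKE",
                "COM_HTN",
                "COM_COPD",
                "COM_ASTHMA",
                "COM_DEPRESSION",
                "COM_DYSPEPSIA",
            },
            "lifestyle": {
                "LIFE_SMOK_NEVER",
                "LIFE_SMOK_CURRENT",
                "LIFE_SMOK_FORMER",
                "LIFE_BMI_15_19",
                "LIFE_BMI_20_24",
                "LIFE_BMI_25_29",
                "LIFE_BMI_GE30",
                "LIFE_ALC_NONE",
                "LIFE_ALC_LOW",
                "LIFE_ALC_MOD",
                "LIFE_ALC_HIGH",
            },
            "encounter": {"ENC_VISIT"},
        }
    )


def load_codelist(path: str | Path) -> CodeList:
    """Load a code list from CSV with header ``code,category``.

    Duplicates within a category are dropped; the same code under two
    categories is a configuration error.
    """
    path = Path(path)
    cats: dict[str, set[str]] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"empty code-list file: {path}")
        if [c.strip().lower() for c in header[:2]] != ["code", "category"]:
            raise ValueError(
                f"code-list file {path}: expected header 'code,category', got {header!r}"
            )
        n_rows = 0
        for row in reader:
            if not row or not row[0].strip():
                continue
            code, cat = row[0].strip(), row[1].strip().lower()
            cats.setdefault(cat, set()).add(code)
            n_rows += 1
        if n_rows == 0:
            raise ValueError(f"code-list file {path} contains no codes")
    return CodeList(cats)


def save_codelist(codelist: CodeList, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["code", "category"])
        for cat in sorted(codelist.categories):
            for code in sorted(codelist.categories[cat]):
                writer.writerow([code, cat])
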