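"""Single and Nemerow composite pollution indices with grade classification.

The single pollution index (SPI) of a metal is its concentration divided by
a regulatory reference standard, P_i = C_i / S_i. The Nemerow composite
pollution index (NCPI) aggregates the per-metal SPIs of one sample as

    NCPI = sqrt((max_i P_i^2 + mean_i P_i^2) / 2),

emphasizing the worst single metal while retaining the average burden.
Reference standards are configuration: the shipped defaults are the
GB 15618-2018 agricultural-soil risk screening values (mg/kg), which depend
on the sample's pH class. They are externally sourced regulatory values,
supplied here as a convenience, and can be overridden per metal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_STANDARDS",
    "SPI_GRADE_LABELS",
    "NCPI_GRADE_LABELS",
    "StandardsTable",
    "PollutionAssessment",
    "spi",
    "ncpi",
    "classify_spi",
    "classify_ncpi",
    "assess",
    "grade_percentages",
    "summarize_grades",
]

# GB 15618-2018 risk screening values (farmland other than paddy), mg/kg,
# keyed by pH class upper bounds 5.5 / 6.5 / 7.5 / inf
_PH_EDGES = (5.5, 6.5, 7.5, np.inf)
DEFAULT_STANDARDS = {
    "Cd": (0.3, 0.3, 0.3, 0.6),
    "As": (40.0, 40.0, 30.0, 25.0),
    "Pb": (70.0, 90.0, 120.0, 170.0),
    "Cr": (150.0, 150.0, 200.0, 250.0),
    "Ni": (60.0, 70.0, 100.0, 190.0),
}

SPI_GRADE_LABELS = ("Pi<=1", "1<Pi<=2", "2<Pi<=3", "3<Pi<=5", "5<Pi")
NCPI_GRADE_LABELS = (
    "Safety",
    "Alert",
    "Slight pollution",
    "Moderate pollution",
    "Severe pollution",
)

_SPI_EDGES = (1.0, 2.0, 3.0, 5.0)
_NCPI_EDGES = (0.7, 1.0, 2.0, 3.0)


@dataclass
class StandardsTable:
    """Per-metal reference standards, optionally pH-class dependent."""

    values: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_STANDARDS)
    )

    def lookup(self, metal: str, ph: float | np.ndarray) -> np.ndarray:
        """Standard S_i (mg/kg) for one metal at the given pH value(s)."""
        row = np.asarray(self.values[metal], dtype=float)
        if row.size == 1:
            return np.broadcast_to(row[0], np.shape(ph)).astype(float) if np.ndim(ph) else row[0]
        cls = np.digitize(np.asarray(ph, dtype=float), _PH_EDGES[:-1], right=True)
        out = row[cls]
        return out if np.ndim(ph) else float(out)


def spi(concentration, standard):
    """Single pollution index P_i = C_i / S_i (unitless)."""
    concentration = np.asarray(concentration, dtype=float)
    standard = np.asarray(standard, dtype=float)
    if np.any(standard <= 0):
        raise ValueError("reference standard must be > 0")
    if np.any(concentration < 0):
        raise ValueError("concentration must be >= 0")
    out = concentration / standard
    return out if out.ndim else float(out)


def ncpi(spi_vector) -> float:
    """Nemerow composite index sqrt((max(P)^2 + mean(P)^2) / 2)."""
    p = np.asarray(spi_vector, dtype=float)
    if p.size == 0:
        raise ValueError("SPI vector must be non-empty")
    if np.any(p < 0):
        raise ValueError("SPI values must be >= 0")
    return float(np.sqrt((p.max() ** 2 + p.mean() ** 2) / 2.0))


def classify_spi(P) -> np.ndarray | int:
    """Grade 1..5 on the half-open bins Pi<=1, 1<Pi<=2, 2<Pi<=3, 3<Pi<=5, 5<Pi."""
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("SPI must be >= 0")
    grade = np.digitize(P, _SPI_EDGES, right=True) + 1
    return grade if grade.ndim else int(grade)


def classify_ncpi(N) -> np.ndarray | str:
    """Nemerow grade: Safety <=0.7 < Alert <=1 < Slight <=2 < Moderate <=3 < Severe."""
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("NCPI must be >= 0")
    idx = np.digitize(N, _NCPI_EDGES, right=True)
    labels = np.asarray(NCPI_GRADE_LABELS)[idx]
    return labels if labels.ndim else str(labels)


@dataclass
class PollutionAssessment:
    """Per-sample SPI vectors, NCPI, grades and the standards used."""

    table: pd.DataFrame  # id, per-metal spi & grade, ncpi, ncpi_grade
    metals: tuple[str, ...]
    standards: StandardsTable

    def __post_init__(self):
        ncpi_col = self.table["ncpi"].to_numpy()
        spi_cols = self.table[[f"{m}_spi" for m in self.metals]].to_numpy()
        # NCPI >= max(P)/sqrt(2) and >= mean(P)/sqrt(2) by construction
        if np.any(ncpi_col + 1e-12 < spi_cols.max(axis=1) / np.sqrt(2)):
            raise ValueError("NCPI inconsistent with SPI vector")


def assess(
    samples: pd.DataFrame,
    metals: tuple[str, ...],
    standards: StandardsTable | None = None,
    suffix: str = "_lab",
) -> PollutionAssessment:
    """Compute per-sample SPIs, grades, NCPI and its grade for a sample table."""
    if standards is None:
        standards = StandardsTable()
    out = {"id": samples["id"].to_numpy() if "id" in samples else np.arange(len(samples))}
    ph = samples["pH"].to_numpy(dtype=float) if "pH" in samples else np.full(len(samples), np.nan)
    spis = []
    for m in metals:
        conc = samples[f"{m}{suffix}"].to_numpy(dtype=float)
        s = standards.lookup(m, ph)
        p = spi(conc, s)
        out[f"{m}_spi"] = p
        out[f"{m}_grade"] = classify_spi(p)
        spis.append(p)
    spis = np.column_stack(spis)
    out["ncpi"] = np.sqrt((spis.max(axis=1) ** 2 + spis.mean(axis=1) ** 2) / 2.0)
    out["ncpi_grade"] = classify_ncpi(out["ncpi"])
    return PollutionAssessment(pd.DataFrame(out), tuple(metals), standards)


def grade_percentages(counts) -> tuple[np.ndarray, np.ndarray]:
    """Counts per grade -> (counts, percentages rounded to 2 decimals)."""
    counts = np.asarray(counts, dtype=int)
    n = counts.sum()
    if n == 0:
        raise ValueError("empty grade counts")
    return counts, np.round(100.0 * counts / n, 2)


def summarize_grades(assessment: PollutionAssessment) -> dict[str, pd.DataFrame]:
    """Per-grade counts and percentages for each metal's SPI and for the NCPI."""
    tbl = assessment.table
    n = len(tbl)
    if n == 0:
        raise ValueError("empty assessment")
    rows = []
    for m in assessment.metals:
        counts = np.bincount(tbl[f"{m}_grade"].to_numpy(), minlength=6)[1:6]
        _, pct = grade_percentages(counts)
        for label, c, p in zip(SPI_GRADE_LABELS, counts, pct):
            rows.append({"element": m, "grade": label, "count": int(c), "percentage": p})
    spi_summary = pd.DataFrame(rows)

    ncpi_counts = np.array(
        [(tbl["ncpi_grade"] == lab).sum() for lab in NCPI_GRADE_LABELS], dtype=int
    )
    _, ncpi_pct = grade_percentages(ncpi_counts)
    ncpi_summary = pd.DataFrame(
        {"grade": NCPI_GRADE_LABELS, "count": ncpi_counts, "percentage": ncpi_pct}
    )
    return {"spi": spi_summary, "ncpi": ncpi_summary}
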