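"""Adduct-based putative annotation of m/z values and tabular pathway mapping.

Discriminatory m/z values are matched against a local compound table
(identifier, name, elemental formula, pathway memberships) by expanding
each compound's neutral monoisotopic mass into the ionization-mode
appropriate adducts ([M+H]+, [M+Na]+, [M+K]+ in positive mode; [M-H]-,
[M+Cl]- in negative mode) and accepting matches within a ppm tolerance
referenced to the theoretical adduct m/z.  Annotation is putative: one
query may hit several (compound, adduct) pairs.  Pathway mapping
aggregates annotated compounds per pathway with their log2 fold changes
clipped to a reporting band.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: IUPAC monoisotopic masses of the lightest stable isotope, in Da.
MONOISOTOPIC = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "F": 18.99840322,
    "Mg": 23.9850417,
    "Ca": 39.96259098,
    "Fe": 55.9349375,
    "Zn": 63.9291422,
}

#: CODATA electron mass in Da.
ELECTRON = 0.00054857990907

#: Ion-mode adduct mass shifts in Da with explicit electron-mass
#: accounting: cation shifts are element mass minus the electron,
#: anion shifts gain one.  [M+H]+ is the CODATA proton mass.
ADDUCTS = {
    "[M+H]+": (MONOISOTOPIC["H"] - ELECTRON, "positive"),
    "[M+Na]+": (MONOISOTOPIC["Na"] - ELECTRON, "positive"),
    "[M+K]+": (MONOISOTOPIC["K"] - ELECTRON, "positive"),
    "[M-H]-": (-(MONOISOTOPIC["H"] - ELECTRON), "negative"),
    "[M+Cl]-": (MONOISOTOPIC["Cl"] + ELECTRON, "negative"),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse an elemental formula like ``C28H37N5O7`` into an element-count map."""
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        pos = match.end()
        element, digits = match.groups()
        n = int(digits) if digits else 1
        if n <= 0:
            raise ValueError(f"non-positive count for {element} in {text!r}")
        counts[element] = counts.get(element, 0) + n
    if pos != len(text) or not counts:
        raise ValueError(f"cannot parse formula {text!r}")
    return counts


def format_formula(counts: dict[str, int]) -> str:
    """Canonical Hill-order text: C first, then H, then other elements alphabetically."""
    order = []
    if "C" in counts:
        order.append("C")
        if "H" in counts:
            order.append("H")
        order += sorted(e for e in counts if e not in ("C", "H"))
    else:
        order = sorted(counts)
    return "".join(f"{e}{counts[e] if counts[e] != 1 else ''}" for e in order)


def monoisotopic_mass(formula: dict[str, int] | str) -> float:
    """Neutral monoisotopic mass in Da of an elemental formula."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    mass = 0.0
    for element, count in formula.items():
        if element not in MONOISOTOPIC:
            raise KeyError(f"no monoisotopic mass for element {element!r}")
        mass += MONOISOTOPIC[element] * count
    return mass


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """Theoretical m/z of a singly charged adduct of a neutral mass."""
    if adduct not in ADDUCTS:
        raise KeyError(f"unknown adduct {adduct!r}; known: {sorted(ADDUCTS)}")
    return neutral_mass + ADDUCTS[adduct][0]


def adducts_for_mode(mode: str) -> list[str]:
    out = [a for a, (_, m) in ADDUCTS.items() if m == mode]
    if not out:
        raise ValueError(f"unknown ionization mode {mode!r}")
    return out


def load_compound_table(path) -> pd.DataFrame:
    """Read a compound table TSV: compound_id, name, formula, pathway_ids (;-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"compound_id", "name", "formula", "pathway_ids"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"compound table missing columns: {sorted(missing)}")
    if df["compound_id"].duplicated().any():
        raise ValueError("duplicate compound_id in compound table")
    return df


def compound_pathways(row_or_text) -> list[str]:
    text = row_or_text if isinstance(row_or_text, str) else row_or_text["pathway_ids"]
    return [p for p in str(text).split(";") if p]


def annotate_mz(
    queries,
    table: pd.DataFrame,
    mode: str,
    ppm_tol: float = 2.0,
) -> tuple[pd.DataFrame, list[float]]:
    """Match query m/z values to compound adducts within a ppm tolerance.

    Returns (hits, unannotated).  Hits carry query_mz, compound_id,
    adduct, theoretical_mz and the signed ppm_error referenced to the
    theoretical m/z, sorted by |ppm_error| then compound_id; hit order is
    independent of compound-table row order.
    """
    if table.empty:
        raise ValueError("compound table is empty")
    queries = np.asarray(list(queries), dtype=float)
    adducts = adducts_for_mode(mode)

    theo = []
    for _, row in table.iterrows():
        mass = monoisotopic_mass(row["formula"])
        for adduct in adducts:
            theo.append((row["compound_id"], adduct, adduct_mz(mass, adduct)))
    theo_df = pd.DataFrame(theo, columns=["compound_id", "adduct", "theoretical_mz"])

    records = []
    annotated = np.zeros(queries.size, dtype=bool)
    theo_mz = theo_df["theoretical_mz"].to_numpy()
    for i, q in enumerate(queries):
        ppm = (q - theo_mz) / theo_mz * 1e6
        within = np.flatnonzero(np.abs(ppm) <= ppm_tol)
        for j in within:
            records.append((q, theo_df.at[j, "compound_id"], theo_df.at[j, "adduct"],
                            theo_mz[j], ppm[j]))
        annotated[i] = within.size > 0

    hits = pd.DataFrame(
        records,
        columns=["query_mz", "compound_id", "adduct", "theoretical_mz", "ppm_error"],
    )
    if not hits.empty:
        hits = hits.reindex(
            hits.assign(abs_ppm=hits["ppm_error"].abs())
            .sort_values(["abs_ppm", "compound_id"], kind="stable")
            .index
        ).reset_index(drop=True)
    unannotated = queries[~annotated].tolist()
    return hits, unannotated


def unique_annotated_masses(hits: pd.DataFrame) -> int:
    """Number of distinct query m/z values with at least one hit."""
    return int(hits["query_mz"].nunique()) if not hits.empty else 0


@dataclass
class PathwayReport:
    summary: pd.DataFrame       # one row per pathway (zero-count rows included)
    members: pd.DataFrame       # one row per (pathway, compound)


def map_to_pathways(
    hits: pd.DataFrame,
    stats_df: pd.DataFrame,
    table: pd.DataFrame,
    pathways: pd.DataFrame,
    clip: float = 5.0,
) -> PathwayReport:
    """Tabular pathway mapping of annotated discriminatory compounds.

    Each annotated compound inherits the log2FC of its best (lowest
    |ppm error|) query feature, clipped to [-clip, +clip] for reporting,
    with a direction label: resistant_up (log2FC > 0), susceptible_up
    (log2FC < 0) or unchanged.  ``pathways`` must have columns
    pathway_id and pathway_name; pathways with no annotated members are
    reported with count 0, not omitted.
    """
    fc_by_mz = (stats_df.drop_duplicates("feature_mz")
                .set_index("feature_mz")["log2fc"])
    memberships = table.set_index("compound_id")["pathway_ids"]

    compound_rows = {}
    if not hits.empty:
        best = hits.loc[hits.assign(abs_ppm=hits["ppm_error"].abs())
                        .groupby("compound_id")["abs_ppm"].idxmin()]
        for _, row in best.iterrows():
            cid = row["compound_id"]
            fc = float(fc_by_mz.get(row["query_mz"], np.nan))
            clipped = float(np.clip(fc, -clip, clip)) if np.isfinite(fc) else np.nan
            if not np.isfinite(fc) or fc == 0:
                direction = "unchanged"
            elif fc > 0:
                direction = "resistant_up"
            else:
                direction = "susceptible_up"
            compound_rows[cid] = (row["query_mz"], fc, clipped, direction)

    member_records = []
    summary_records = []
    for _, prow in pathways.iterrows():
        pid, pname = prow["pathway_id"], prow["pathway_name"]
        count = 0
        for cid, (qmz, fc, clipped, direction) in compound_rows.items():
            if pid in compound_pathways(str(memberships.get(cid, ""))):
                count += 1
                member_records.append((pid, pname, cid, qmz, fc, clipped, direction))
        summary_records.append((pid, pname, count))

    summary = pd.DataFrame(summary_records,
                           columns=["pathway_id", "pathway_name", "n_compounds"])
    members = pd.DataFrame(
        member_records,
        columns=["pathway_id", "pathway_name", "compound_id", "query_mz",
                 "log2fc", "log2fc_clipped", "direction"],
    )
    return PathwayReport(summary=summary, members=members)
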