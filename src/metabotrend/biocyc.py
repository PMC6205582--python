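"""Converter for PathwayTools/BioCyc flat-file dumps.

BioCyc attribute-value files (``compounds.dat``, ``pathways.dat``) are records
separated by ``//`` lines, each record a sequence of ``ATTR - VALUE`` lines.
This module flattens the subset needed here — compound monoisotopic masses and
pathway memberships — into the long-format CSV tables consumed by
:func:`metabotrend.core_data.load_knowledge_base`.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .core_data import empty_pathways


def _iter_records(path: str | Path):
    record: dict[str, list[str]] = {}
    with open(path, encoding="utf-8", errors="replace") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#") or not line.strip():
                continue
            if line.startswith("//"):
                if record:
                    yield record
                record = {}
                continue
            if " - " in line:
                attr, value = line.split(" - ", 1)
                record.setdefault(attr.strip(), []).append(value.strip())
    if record:
        yield record


def compounds_from_biocyc(path: str | Path) -> pd.DataFrame:
    """Parse a BioCyc ``compounds.dat`` into the compound CSV table.

    Records without a ``MONOISOTOPIC-MW`` (hypothetical compounds with no
    mass) are skipped, since accurate-mass annotation cannot use them.
    """
    rows = []
    for rec in _iter_records(path):
        cid = rec.get("UNIQUE-ID", [None])[0]
        mw = rec.get("MONOISOTOPIC-MW", [None])[0]
        if cid is None or mw is None:
            continue
        name = rec.get("COMMON-NAME", [cid])[0]
        try:
            mass = float(mw)
        except ValueError:
            continue
        rows.append({"compound_id": cid, "name": name, "monoisotopic_mass": mass})
    return pd.DataFrame(rows).set_index("compound_id")


def pathways_from_biocyc(path: str | Path, known_compounds: set[str] | None = None) -> pd.DataFrame:
    """Parse a BioCyc ``pathways.dat`` into the long-format pathway table.

    ``COMPOUND-LIST`` (or ``SPECIES``/``IN-PATHWAY`` style member attributes)
    entries not present in *known_compounds* are dropped when the set is given,
    so the resulting KnowledgeBase always cross-references cleanly.
    """
    rows = []
    for rec in _iter_records(path):
        pid = rec.get("UNIQUE-ID", [None])[0]
        if pid is None:
            continue
        name = rec.get("COMMON-NAME", [pid])[0]
        members = rec.get("COMPOUND-LIST", [])
        for cid in members:
            if known_compounds is not None and cid not in known_compounds:
                continue
            rows.append({"pathway_id": pid, "pathway_name": name, "compound_id": cid})
    if not rows:
        return empty_pathways()
    return pd.DataFrame(rows)


def convert_biocyc(
    compounds_dat: str | Path,
    pathways_dat: str | Path,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Flatten a BioCyc dump to ``compounds.csv`` + ``pathways.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    compounds = compounds_from_biocyc(compounds_dat)
    pathways = pathways_from_biocyc(pathways_dat, set(compounds.index))
    paths = {"compounds": out / "compounds.csv", "pathways": out / "pathways.csv"}
    compounds.to_csv(paths["compounds"], index_label="compound_id")
    pathways.to_csv(paths["pathways"], index=False)
    return paths
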