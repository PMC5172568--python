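"""Reading pair tables and writing Skyline / instrument list files.

The transition list follows the Skyline *small molecule* import schema with
exactly seven tab-separated columns, in this order:

    Precursor Name, Precursor m/z, Product m/z, Precursor Charge,
    Product Charge, Molecule List Name, Product Name

The isolation list follows the Q-Exactive scheduled-PRM inclusion-list CSV
dialect (Mass [m/z], Formula, Species, CS [z], Polarity, Start [min],
End [min]). All m/z values are written with four decimals; output is
byte-stable for identical inputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .mass_core import CARBAMIDOMETHYL, Modification
from .crosslink_model import (
    BDP_LINKER,
    CrossLinkedPair,
    PIRLinker,
    Transition,
    make_pair,
    precursor_mz,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TRANSITION_COLUMNS",
    "ISOLATION_COLUMNS",
    "PairTableError",
    "read_pair_table",
    "write_skyline_transition_list",
    "read_skyline_transition_list",
    "write_isolation_list",
]

TRANSITION_COLUMNS = (
    "Precursor Name",
    "Precursor m/z",
    "Product m/z",
    "Precursor Charge",
    "Product Charge",
    "Molecule List Name",
    "Product Name",
)

ISOLATION_COLUMNS = (
    "Mass [m/z]",
    "Formula",
    "Species",
    "CS [z]",
    "Polarity",
    "Start [min]",
    "End [min]",
)

_MANDATORY = (
    "alpha_sequence",
    "alpha_link_site",
    "beta_sequence",
    "beta_link_site",
    "precursor_charge",
)


class PairTableError(ValueError):
    """Fatal pair-table problem (missing mandatory column, unreadable file)."""


def _parse_mods(cell, registry: Dict[str, Modification]) -> Tuple:
    """Parse 'pos:Name;pos:Name' cells into (position, Modification) tuples."""
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return ()
    out = []
    for token in str(cell).split(";"):
        token = token.strip()
        if not token:
            continue
        pos_s, _, name = token.partition(":")
        if name not in registry:
            raise ValueError(f"unknown modification {name!r}")
        out.append((int(pos_s), registry[name]))
    return tuple(out)


def read_pair_table(
    path,
    linker: PIRLinker = BDP_LINKER,
    modification_registry: Optional[Dict[str, Modification]] = None,
    fixed_mods: Sequence[Modification] = (CARBAMIDOMETHYL,),
) -> Tuple[List[CrossLinkedPair], List[str]]:
    """Read a tab-delimited cross-linked-pair table.

    Returns ``(pairs, errors)``: rows that fail validation are skipped and
    reported with their line numbers; valid rows are still returned.
    Mandatory columns: alpha_sequence, alpha_link_site, beta_sequence,
    beta_link_site, precursor_charge. Optional: pair_name, observed_mz,
    channel, group, alpha_modifications, beta_modifications.
    """
    registry = dict(modification_registry or {})
    registry.setdefault(CARBAMIDOMETHYL.name, CARBAMIDOMETHYL)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # unreadable file is fatal
        raise PairTableError(f"cannot read pair table {path}: {exc}") from exc
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise PairTableError(f"pair table {path} missing mandatory columns: {missing}")

    pairs: List[CrossLinkedPair] = []
    errors: List[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            observed = row.get("observed_mz")
            observed_mz = None if observed is None or pd.isna(observed) else float(observed)
            channel = row.get("channel")
            channel = "light" if channel is None or pd.isna(channel) else str(channel)
            group = row.get("group")
            group = "xlink" if group is None or pd.isna(group) else str(group)
            pair = make_pair(
                str(row["alpha_sequence"]).strip(),
                int(row["alpha_link_site"]),
                str(row["beta_sequence"]).strip(),
                int(row["beta_link_site"]),
                charge=int(row["precursor_charge"]),
                observed_mz=observed_mz,
                channel=channel,
                linker=linker,
                fixed_mods=fixed_mods,
                extra_mods_alpha=_parse_mods(row.get("alpha_modifications"), registry),
                extra_mods_beta=_parse_mods(row.get("beta_modifications"), registry),
                group=group,
            )
            pairs.append(pair)
        except Exception as exc:
            msg = f"line {line}: {exc}"
            errors.append(msg)
            logger.warning("pair table row skipped: %s", msg)
    return pairs, errors


def write_pair_table(pairs: Sequence[CrossLinkedPair], path) -> None:
    """Write pairs back out in the tab-delimited pair-table schema."""
    cols = [
        "pair_name", "alpha_sequence", "alpha_link_site", "beta_sequence",
        "beta_link_site", "precursor_charge", "observed_mz", "channel", "group",
    ]
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(cols) + "\n")
        for p in pairs:
            obs = "" if p.observed_mz is None else f"{p.observed_mz:.4f}"
            fh.write(
                "\t".join(
                    [
                        p.pair_name,
                        p.alpha.sequence,
                        str(p.alpha.link_site),
                        p.beta.sequence,
                        str(p.beta.link_site),
                        str(p.precursor_charge),
                        obs,
                        p.channel,
                        p.group,
                    ]
                )
                + "\n"
            )


def write_skyline_transition_list(
    pairs: Sequence[CrossLinkedPair],
    transitions: Sequence[Transition],
    path,
    mode: str = "most_abundant",
    molecule_list_name: Optional[str] = None,
) -> None:
    """Write the 7-column Skyline small-molecule transition list (TSV).

    One row per transition; precursor m/z computed per pair under ``mode``
    and repeated on each of its rows; all m/z to 4 decimals; LF endings.
    """
    by_name = {p.pair_name: p for p in pairs}
    unknown = {t.pair_name for t in transitions} - set(by_name)
    if unknown:
        raise ValueError(f"transitions reference unknown pairs: {sorted(unknown)}")
    prec_mz = {name: precursor_mz(p, mode) for name, p in by_name.items()}
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(TRANSITION_COLUMNS) + "\n")
        for t in transitions:
            p = by_name[t.pair_name]
            fh.write(
                "\t".join(
                    [
                        t.pair_name,
                        f"{prec_mz[t.pair_name]:.4f}",
                        f"{t.product_mz:.4f}",
                        str(p.precursor_charge),
                        str(t.product_charge),
                        molecule_list_name or p.group,
                        t.product_name,
                    ]
                )
                + "\n"
            )


def read_skyline_transition_list(path) -> pd.DataFrame:
    """Parse a transition list back into a DataFrame with typed m/z and charges."""
    df = pd.read_csv(path, sep="\t")
    if tuple(df.columns) != TRANSITION_COLUMNS:
        raise ValueError(
            f"unexpected transition-list columns {tuple(df.columns)!r}; "
            f"expected {TRANSITION_COLUMNS!r}"
        )
    return df.astype(
        {
            "Precursor m/z": float,
            "Product m/z": float,
            "Precursor Charge": int,
            "Product Charge": int,
        }
    )


def write_isolation_list(
    pairs: Sequence[CrossLinkedPair],
    path,
    mode: str = "most_abundant",
    rt_windows: Optional[Dict[str, Tuple[float, float]]] = None,
) -> int:
    """Write the Q-Exactive inclusion-list CSV; returns the number of rows.

    One row per pair (precursor), sorted by m/z; duplicates at identical
    (m/z, charge) are removed with a warning. ``rt_windows`` maps pair_name
    to (start, end) minutes for scheduled PRM; blank when absent.
    """
    rows = []
    seen = set()
    for p in pairs:
        mz = precursor_mz(p, mode)
        key = (round(mz, 4), p.precursor_charge)
        if key in seen:
            warnings.warn(f"duplicate precursor {key} dropped from isolation list")
            continue
        seen.add(key)
        window = (rt_windows or {}).get(p.pair_name)
        rows.append((mz, p.precursor_charge, window))
    rows.sort(key=lambda r: r[0])
    with open(path, "w", newline="") as fh:
        fh.write(",".join(ISOLATION_COLUMNS) + "\n")
        for mz, z, window in rows:
            start = "" if window is None else f"{window[0]:.2f}"
            end = "" if window is None else f"{window[1]:.2f}"
            fh.write(f"{mz:.4f},,,{z},Positive,{start},{end}\n")
    return len(rows)
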