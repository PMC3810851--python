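"""Reading, writing and normalisation of GWAS summary statistics.

A summary-statistics file is a tab-delimited table with a header, one row per
SNP, carrying at minimum a chromosome, a 1-based position and the two alleles,
plus either a signed Z-score or a two-sided p-value with an effect direction.
Column names are configurable through a column map; the defaults are
CHR, POS, A1, A2, Z, P, DIR.  A1 is the effect allele: a positive Z means the
A1 allele is associated with a larger trait value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

log = logging.getLogger(__name__)

#: Default header names for each logical column.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "chrom": "CHR",
    "pos": "POS",
    "a1": "A1",
    "a2": "A2",
    "z": "Z",
    "p": "P",
    "direction": "DIR",
}

_VALID_ALLELES = frozenset("ACGT")

#: Smallest two-sided p-value convertible to a finite double-precision Z.
MIN_P = 1e-300


class SumStatsError(ValueError):
    """Malformed or inconsistent summary-statistics input."""


@dataclass
class SumStatRecord:
    """One SNP's identity, alleles and association statistic.

    Attributes
    ----------
    chrom : str
        Chromosome label, normalised (any leading ``chr`` stripped).
    pos : int
        1-based base-pair position.
    a1, a2 : str
        Effect allele and other allele (single bases, A/C/G/T).
    z : float or None
        Signed standard-normal statistic; ``None`` when unobserved.
    p : float or None
        Two-sided p-value in (0, 1].
    direction : int or None
        Sign of the effect (+1/-1); required when only ``p`` is given.
    typed : bool
        Whether the SNP was measured in the study.
    """

    chrom: str
    pos: int
    a1: str
    a2: str
    z: float | None = None
    p: float | None = None
    direction: int | None = None
    typed: bool = True

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        self.a1 = self.a1.upper()
        self.a2 = self.a2.upper()
        if self.pos < 1:
            raise SumStatsError(f"position must be >= 1, got {self.pos}")
        if self.a1 == self.a2:
            raise SumStatsError(
                f"alleles must differ at {self.chrom}:{self.pos} ({self.a1}/{self.a2})"
            )
        if not (set(self.a1) <= _VALID_ALLELES and set(self.a2) <= _VALID_ALLELES):
            raise SumStatsError(
                f"non-ACGT allele at {self.chrom}:{self.pos} ({self.a1}/{self.a2})"
            )


def normalize_chrom(chrom: str | int) -> str:
    """Normalise a chromosome label: stringify and strip any ``chr`` prefix."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


def p_to_z(p: float, direction: int) -> float:
    """Convert a two-sided p-value and effect direction to a signed Z-score.

    Returns ``direction * Phi^-1(1 - p/2)`` where ``Phi`` is the standard
    normal CDF, so ``p=1`` maps to 0 and small p to large abs(Z).  P-values
    below ~1e-300 (the smallest giving a finite double-precision quantile)
    are clamped with a warning.
    """
    if direction not in (1, -1):
        raise SumStatsError(f"direction must be +1 or -1, got {direction!r}")
    if not (0.0 < p <= 1.0):
        raise SumStatsError(f"p-value must be in (0, 1], got {p!r}")
    if p < MIN_P:
        log.warning("p-value %.3g below %.0g; clamping", p, MIN_P)
        p = MIN_P
    # Phi^-1(1 - p/2) == -Phi^-1(p/2)
    return float(direction * -special.ndtri(p / 2.0))


def z_to_p(z: float) -> float:
    """Two-sided p-value of a signed Z-score: ``2 * (1 - Phi(|z|))``."""
    if not math.isfinite(z):
        raise SumStatsError(f"z must be finite, got {z!r}")
    return float(2.0 * special.ndtr(-abs(z)))


def _require_columns(columns: Iterable[str], needed: Mapping[str, str]) -> None:
    missing = [name for name in needed.values() if name not in columns]
    if missing:
        raise SumStatsError(f"missing mandatory column(s): {', '.join(missing)}")


def read_sumstats(
    path, column_map: Mapping[str, str] | None = None
) -> list[SumStatRecord]:
    """Read a tab-delimited summary-statistics file into sorted records.

    Parameters
    ----------
    path : str or path-like
        File with a header row; ``#`` lines are treated as comments.
    column_map : mapping, optional
        Overrides for :data:`DEFAULT_COLUMN_MAP` (logical name -> header name).

    Returns
    -------
    list of SumStatRecord
        Sorted by (chrom, pos).  Rows lacking both a parseable Z and a
        (p, direction) pair are skipped with a logged count; duplicate
        (chrom, pos, allele-pair) rows raise :class:`SumStatsError`.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    _require_columns(df.columns, {k: cmap[k] for k in ("chrom", "pos", "a1", "a2")})
    has_z = cmap["z"] in df.columns
    has_p = cmap["p"] in df.columns
    has_dir = cmap["direction"] in df.columns
    if not has_z and not (has_p and has_dir):
        raise SumStatsError(
            f"need either a {cmap['z']} column or both {cmap['p']} and "
            f"{cmap['direction']} columns"
        )

    records: list[SumStatRecord] = []
    seen: set[tuple[str, int, frozenset[str]]] = set()
    n_skipped = 0
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        z = _parse_float(row.get(cmap["z"])) if has_z else None
        p = _parse_float(row.get(cmap["p"])) if has_p else None
        d = _parse_direction(row.get(cmap["direction"])) if has_dir else None
        if z is None and (p is None or d is None):
            n_skipped += 1
            continue
        if z is not None and p is not None:
            z_from_p = p_to_z(p, 1 if z >= 0 else -1)
            denom = max(abs(z), abs(z_from_p), 1e-12)
            if abs(abs(z) - abs(z_from_p)) / denom > 1e-3:
                log.warning(
                    "Z (%.4g) and p (%.3g) inconsistent at %s:%s; trusting Z",
                    z, p, row[cmap["chrom"]], row[cmap["pos"]],
                )
        if z is None:
            z = p_to_z(p, d)
        rec = SumStatRecord(
            chrom=row[cmap["chrom"]],
            pos=int(row[cmap["pos"]]),
            a1=str(row[cmap["a1"]]),
            a2=str(row[cmap["a2"]]),
            z=z,
            p=p if p is not None else z_to_p(z),
            direction=d,
        )
        key = (rec.chrom, rec.pos, frozenset((rec.a1, rec.a2)))
        if key in seen:
            raise SumStatsError(
                f"duplicate record at {rec.chrom}:{rec.pos} ({rec.a1}/{rec.a2})"
            )
        seen.add(key)
        records.append(rec)
    if n_skipped:
        log.warning("skipped %d row(s) with no usable statistic", n_skipped)

    keys = [( _chrom_sort_key(r.chrom), r.pos) for r in records]
    if keys != sorted(keys):
        log.warning("input not sorted by (chrom, pos); sorting")
        records = [r for _, r in sorted(zip(keys, records), key=lambda t: t[0])]
    return records


def _parse_float(value) -> float | None:
    if value is None:
        return None
    s = str(value).strip()
    if s in ("", "NA", "NaN", "nan", "."):
        return None
    try:
        x = float(s)
    except ValueError:
        return None
    return x if math.isfinite(x) else None


def _parse_direction(value) -> int | None:
    if value is None:
        return None
    s = str(value).strip()
    if s in ("+", "+1", "1"):
        return 1
    if s in ("-", "-1"):
        return -1
    return None


def _chrom_sort_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def write_results(records: Sequence, path, header_lines: Sequence[str] = ()) -> None:
    """Write imputation results as a tab-delimited table.

    Columns: CHR, POS, A1, A2, Z, P, R2PRED, STATUS, where STATUS is one of
    ``typed``/``imputed``/``skipped``.  Skipped records (quality below the
    reporting threshold) have empty Z and P fields.  Z is written with six
    significant digits so typed records round-trip through
    :func:`read_sumstats`.  Optional ``header_lines`` are emitted as ``#``
    comments before the header.
    """
    if not records:
        raise SumStatsError("no records to write")
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("CHR\tPOS\tA1\tA2\tZ\tP\tR2PRED\tSTATUS\n")
        for r in records:
            status = getattr(r, "status", "typed")
            z = getattr(r, "z_imp", None)
            if z is None:
                z = getattr(r, "z", None)
            if status == "skipped" or z is None:
                z_str = p_str = ""
            else:
                z_str = f"{z:.6g}"
                p_str = f"{z_to_p(z):.6g}"
            r2 = getattr(r, "r2pred", None)
            r2_str = "" if r2 is None else f"{r2:.6g}"
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.a1}\t{r.a2}\t{z_str}\t{p_str}\t{r2_str}\t{status}\n"
            )
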