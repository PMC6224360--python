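"""Tab-separated table formats and run configuration.

All tables are tab-delimited with a mandatory header row and decimal points,
so allele symbols round-trip unambiguously.

* genotype table (long): ``progeny_id  locus  allele  dosage`` — one row per
  visible allele of a triploid progeny call;
* parent table (long): ``locus  linkage_group  parent  alleles`` with parent
  in {WLM, PON, CHA} and alleles like ``B/C`` (``0`` marks a null);
* gamete matrix: one row per gamete, one column per locus, cells ``A/B``
  (empty = missing);
* counts table (long): ``locus  gamete_class  count`` with class ``A/B``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd
import yaml

from .inference import (
    LocusCounts,
    MaternalGenotype,
    TriploidCall,
    validate_maternal,
)
from .model import NULL_ALLELE, TetraploidGenotype, gamete_class
from .transmission import DissimilarityMatrix, GameteMatrix

__all__ = [
    "AnalysisConfig",
    "load_config",
    "read_genotype_table",
    "write_genotype_table",
    "read_parent_table",
    "write_parent_table",
    "read_counts_table",
    "write_counts_table",
    "write_gamete_matrix",
    "read_gamete_matrix",
    "write_dissimilarity",
    "write_key_values",
]

_GENOTYPE_COLS = ["progeny_id", "locus", "allele", "dosage"]
_PARENT_COLS = ["locus", "linkage_group", "parent", "alleles"]


@dataclass
class AnalysisConfig:
    """Settings of a full pipeline run, loadable from YAML."""

    genotypes: Path
    parents: Path
    outdir: Optional[Path] = None
    seed: int = 0
    distortion_alpha: float = 0.05
    grid_step: float = 0.01
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 < self.distortion_alpha < 1.0:
            raise ValueError("distortion_alpha must lie in (0, 1)")
        if not 0.0 < self.grid_step <= 0.5:
            raise ValueError("grid_step must lie in (0, 0.5]")
        if not 0.0 < self.tol <= 1e-2:
            raise ValueError("tol must lie in (0, 1e-2]")


def load_config(path) -> AnalysisConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    base = Path(path).parent
    known = {"genotypes", "parents", "outdir", "seed", "distortion_alpha",
             "grid_step", "tol"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
    for key in ("genotypes", "parents"):
        if key not in raw:
            raise ValueError(f"{path}: missing required key {key!r}")
        raw[key] = (base / raw[key]).resolve()
    if raw.get("outdir") is not None:
        raw["outdir"] = (base / raw["outdir"]).resolve()
    return AnalysisConfig(**raw)


def _require_columns(df: pd.DataFrame, cols: List[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def read_genotype_table(
    path,
    allowed_nulls: Optional[Mapping[str, int]] = None,
    ploidy: int = 3,
) -> List[TriploidCall]:
    """Parse a long-format triploid genotype table into calls.

    ``allowed_nulls`` maps a locus to the number of null alleles its
    parental constitution can contribute to a gamete (default 0 everywhere),
    relaxing the visible-dosage check accordingly.  Malformed rows fail with
    their line number.
    """
    allowed_nulls = dict(allowed_nulls or {})
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, _GENOTYPE_COLS, path)
    records: Dict[Tuple[str, str], Dict[str, int]] = {}
    first_line: Dict[Tuple[str, str], int] = {}
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header is line 1
        try:
            dosage = int(row.dosage)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}:{line}: dosage {row.dosage!r} is not an integer"
            ) from None
        if dosage < 1:
            raise ValueError(f"{path}:{line}: dosage must be positive")
        if not row.progeny_id or not row.locus or not row.allele:
            raise ValueError(f"{path}:{line}: empty field")
        key = (str(row.progeny_id), str(row.locus))
        rec = records.setdefault(key, {})
        first_line.setdefault(key, line)
        if row.allele in rec:
            raise ValueError(
                f"{path}:{line}: duplicate allele {row.allele!r} for "
                f"{key[0]}/{key[1]}"
            )
        rec[str(row.allele)] = dosage
    calls = []
    for (pid, locus), dosages in records.items():
        total = sum(dosages.values())
        slack = allowed_nulls.get(locus, 0)
        if not ploidy - slack <= total <= ploidy:
            raise ValueError(
                f"{path}:{first_line[(pid, locus)]}: visible dosage {total} for "
                f"{pid}/{locus} incompatible with ploidy {ploidy}"
                + (f" (up to {slack} null(s) allowed)" if slack else "")
            )
        calls.append(TriploidCall(pid, locus, dosages))
    return calls


def write_genotype_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_parent_table(
    path,
) -> Tuple[Dict[str, TetraploidGenotype], Dict[str, MaternalGenotype], Dict[str, int]]:
    """Parse the parent table into tetraploid genotypes, maternal genotypes
    and the locus -> linkage-group map.  Maternal/paternal compatibility is
    checked here (fail fast)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, _PARENT_COLS, path)
    by_locus: Dict[str, Dict[str, Tuple[str, ...]]] = {}
    lg_map: Dict[str, int] = {}
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2
        if row.parent not in ("WLM", "PON", "CHA"):
            raise ValueError(
                f"{path}:{line}: parent must be WLM, PON or CHA, got {row.parent!r}"
            )
        alleles = tuple(str(row.alleles).split("/"))
        if len(alleles) != 2 or not all(alleles):
            raise ValueError(
                f"{path}:{line}: alleles must be two '/'-separated symbols"
            )
        try:
            lg = int(row.linkage_group)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}:{line}: linkage_group {row.linkage_group!r} is not an "
                "integer"
            ) from None
        locus = str(row.locus)
        if locus in lg_map and lg_map[locus] != lg:
            raise ValueError(f"{path}:{line}: conflicting linkage group for {locus}")
        lg_map[locus] = lg
        by_locus.setdefault(locus, {})[str(row.parent)] = alleles
    genotypes: Dict[str, TetraploidGenotype] = {}
    maternal: Dict[str, MaternalGenotype] = {}
    for locus, parents in by_locus.items():
        for who in ("WLM", "PON", "CHA"):
            if who not in parents:
                raise ValueError(f"{path}: locus {locus} lacks a {who} genotype")
        genotypes[locus] = TetraploidGenotype.from_parents(
            locus, parents["WLM"], parents["PON"], lg_map[locus]
        )
        maternal[locus] = MaternalGenotype(locus, parents["CHA"])
        validate_maternal(maternal[locus], genotypes[locus])
    return genotypes, maternal, lg_map


def write_parent_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_counts_table(counts: Mapping[str, LocusCounts], path) -> None:
    rows = []
    for locus in sorted(counts):
        for cls in sorted(counts[locus].counts):
            rows.append(
                {"locus": locus, "gamete_class": "/".join(cls),
                 "count": counts[locus].counts[cls]}
            )
    pd.DataFrame(rows, columns=["locus", "gamete_class", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_counts_table(path) -> Dict[str, LocusCounts]:
    df = pd.read_csv(path, sep="\t", dtype={"locus": str, "gamete_class": str})
    _require_columns(df, ["locus", "gamete_class", "count"], path)
    out: Dict[str, Dict] = {}
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2
        parts = str(row.gamete_class).split("/")
        if len(parts) != 2:
            raise ValueError(
                f"{path}:{line}: gamete_class must be two '/'-separated alleles"
            )
        cls = gamete_class(parts[0], parts[1])
        out.setdefault(str(row.locus), {})[cls] = int(row.count)
    return {locus: LocusCounts(locus, c) for locus, c in out.items()}


def write_gamete_matrix(matrix: GameteMatrix, path) -> None:
    display = matrix.data.map(lambda c: "/".join(c) if c is not None else "")
    display.index.name = "gamete_id"
    display.to_csv(path, sep="\t")


def read_gamete_matrix(
    path,
    origin_maps: Mapping[str, Mapping[str, str]],
    lg_map: Mapping[str, int],
) -> GameteMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gamete_id", dtype=str)

    def parse(cell):
        if cell is None or (isinstance(cell, float)) or cell == "":
            return None
        parts = str(cell).split("/")
        if len(parts) != 2:
            raise ValueError(f"{path}: malformed gamete cell {cell!r}")
        return gamete_class(parts[0], parts[1])

    data = df.map(parse)
    return GameteMatrix(
        data,
        {l: dict(origin_maps[l]) for l in data.columns},
        {l: int(lg_map[l]) for l in data.columns},
    )


def write_dissimilarity(dm: DissimilarityMatrix, path) -> None:
    out = dm.values.copy()
    out.index.name = "gamete_id"
    out.to_csv(path, sep="\t", float_format="%.6f")


def write_key_values(values: Mapping[str, object], path) -> None:
    with open(path, "w") as fh:
        for key, value in values.items():
            fh.write(f"{key}: {value}\n")
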