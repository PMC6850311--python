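"""Text I/O: genotype/phenotype tables, scan configs and result tables.

Two genotype dialects are supported:

* plain TSV — header row of marker IDs with a leading ``sample_id`` column,
  one row per sample, additive codes;
* PLINK-RAW — the ``plink --recode A`` dialect: header
  ``FID IID PAT MAT SEX PHENOTYPE`` followed by one column per marker
  (names may carry an ``_A`` allele suffix), whitespace-separated.

Floats in result tables are written in scientific notation with 10
significant digits so that reruns produce byte-identical files and the
V2/V12 invariance is visible in plain diffs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import GenotypeMatrix, PhenotypeVector
from .exceptions import ParseError

__all__ = [
    "load_genotypes",
    "write_genotypes",
    "load_phenotypes",
    "write_phenotypes",
    "write_results",
    "load_scan_config",
]

FLOAT_FMT = "%.10e"
_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _check_duplicates(ids, what: str, path) -> None:
    seen, dup = set(), []
    for s in ids:
        if s in seen:
            dup.append(s)
        seen.add(s)
    if dup:
        raise ParseError(f"{path}: duplicate {what} ID(s): {sorted(set(dup))}")


def _sniff_dialect(path) -> str:
    with open(path) as fh:
        header = fh.readline().split()
    if header[:6] == _RAW_META:
        return "raw"
    return "tsv"


def load_genotypes(path, dialect: str = "auto") -> GenotypeMatrix:
    """Read a genotype matrix from TSV or PLINK-RAW text.

    Raises :class:`ParseError` (with 1-based line numbers where possible)
    for malformed headers, non-numeric codes or duplicate IDs.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = _sniff_dialect(path)
    if dialect not in ("tsv", "raw"):
        raise ParseError(f"unknown genotype dialect {dialect!r}")

    if dialect == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "sample_id":
            raise ParseError(
                f"{path}:1: malformed TSV genotype header (expected 'sample_id' then "
                "marker IDs)"
            )
        marker_ids = header[1:]
        _check_duplicates(marker_ids, "marker", path)
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        sample_ids = df["sample_id"].tolist()
        body = df.drop(columns="sample_id")
    else:
        with open(path) as fh:
            header = fh.readline().split()
        if header[:6] != _RAW_META:
            raise ParseError(
                f"{path}:1: malformed PLINK-RAW header (expected {' '.join(_RAW_META)})"
            )
        # strip the counted-allele suffix plink appends, e.g. "m0001_A" -> "m0001"
        marker_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in header[6:]]
        _check_duplicates(marker_ids, "marker", path)
        df = pd.read_csv(path, sep=r"\s+", dtype={"FID": str, "IID": str})
        sample_ids = df["IID"].tolist()
        body = df.drop(columns=_RAW_META)

    _check_duplicates(sample_ids, "sample", path)
    codes = body.to_numpy()
    if not np.issubdtype(codes.dtype, np.number):
        for i, row in enumerate(body.itertuples(index=False), start=2):
            for v in row:
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{path}:{i}: non-numeric genotype code {v!r}"
                    ) from None
        raise ParseError(f"{path}: non-numeric genotype codes")
    codes = codes.astype(float)
    if not np.all(np.isfinite(codes)):
        i, j = np.argwhere(~np.isfinite(codes))[0]
        raise ParseError(
            f"{path}:{i + 2}: missing or non-numeric genotype code for marker "
            f"{marker_ids[j]!r}"
        )
    return GenotypeMatrix(sample_ids, marker_ids, codes)


def write_genotypes(geno: GenotypeMatrix, path, dialect: str = "tsv") -> None:
    """Write genotypes as TSV (default) or PLINK-RAW text."""
    path = Path(path)
    if dialect == "tsv":
        df = pd.DataFrame(geno.codes, columns=geno.marker_ids)
        df.insert(0, "sample_id", geno.sample_ids)
        df.to_csv(path, sep="\t", index=False, float_format="%g")
    elif dialect == "raw":
        df = pd.DataFrame(geno.codes, columns=geno.marker_ids)
        meta = pd.DataFrame(
            {
                "FID": geno.sample_ids,
                "IID": geno.sample_ids,
                "PAT": 0,
                "MAT": 0,
                "SEX": 0,
                "PHENOTYPE": -9,
            }
        )
        pd.concat([meta, df], axis=1).to_csv(path, sep=" ", index=False, float_format="%g")
    else:
        raise ParseError(f"unknown genotype dialect {dialect!r}")


def load_phenotypes(path) -> PhenotypeVector:
    """Read a two-column (sample ID, value) TSV; a header row is optional."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            if lineno == 1:
                try:
                    float(parts[1])
                except ValueError:
                    continue  # header row
            try:
                rows.append((parts[0], float(parts[1])))
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric phenotype {parts[1]!r}"
                ) from None
    if not rows:
        raise ParseError(f"{path}: no phenotype rows")
    ids = [r[0] for r in rows]
    _check_duplicates(ids, "sample", path)
    return PhenotypeVector(ids, np.array([r[1] for r in rows]))


def write_phenotypes(pheno: PhenotypeVector, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tvalue\n")
        for s, v in zip(pheno.sample_ids, pheno.values):
            fh.write(f"{s}\t{FLOAT_FMT % v}\n")


def write_results(table: pd.DataFrame, path) -> None:
    """Write a scan results table with fixed float formatting."""
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def load_scan_config(path) -> dict:
    """Read a YAML scan config.

    Recognized keys: ``sigma_beta2``, ``sigma_e2``, ``sets`` (list of
    marker-ID lists) or ``sets_file`` (one whitespace-separated list per
    line), ``center``, and an optional ``block_cov`` mapping with scalar
    ``b11``/``b22`` and sparse ``b12`` triplets
    ``[tested_id, background_id, value]``.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a YAML mapping")
    for key in ("sigma_beta2", "sigma_e2"):
        if key not in cfg:
            raise ParseError(f"{path}: missing required key {key!r}")
    if "sets_file" in cfg:
        sets_path = Path(cfg["sets_file"])
        if not sets_path.is_absolute():
            sets_path = path.parent / sets_path
        with open(sets_path) as fh:
            cfg["sets"] = [line.split() for line in fh if line.strip()]
    if "sets" not in cfg or not cfg["sets"]:
        raise ParseError(f"{path}: no marker sets defined ('sets' or 'sets_file')")
    return cfg
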