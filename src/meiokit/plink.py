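"""PLINK 1 text (.ped/.map) and binary (.bed/.bim/.fam) readers and writers.

Dosages count the A1 allele of the .bim/.map.  The binary codec implements the
SNP-major PLINK 1 layout: magic bytes ``0x6c 0x1b 0x01`` then one record per
variant of ceil(n/4) bytes, two bits per sample, low bits first:

    00 hom A1 (dosage 2)    01 missing
    10 het    (dosage 1)    11 hom A2 (dosage 0)

Trailing unused slots of each record are zero-padded.
"""
from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MarkerPanel, Pedigree, ValidationError

BED_MAGIC = bytes((0x6C, 0x1B, 0x01))

# 2-bit code -> dosage of A1
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    pass


def _sex_to_code(sex: str) -> str:
    return {"male": "1", "female": "2"}.get(sex, "0")


def _code_to_sex(code: str) -> str:
    return {"1": "male", "2": "female"}.get(code, "unknown")


def read_map(path: Path) -> MarkerPanel:
    try:
        rows = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return MarkerPanel((), (), ())
    if rows.empty:
        return MarkerPanel((), (), ())
    if rows.shape[1] < 4:
        raise PlinkFormatError(f"{path}: expected >=4 columns, got {rows.shape[1]}")
    return MarkerPanel(
        tuple(rows[1]),
        tuple(rows[0]),
        tuple(int(p) for p in rows[3]),
    )


def _read_bim(path: Path) -> MarkerPanel:
    try:
        rows = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return MarkerPanel((), (), ())
    if rows.empty:
        return MarkerPanel((), (), ())
    if rows.shape[1] != 6:
        raise PlinkFormatError(f"{path}: .bim needs 6 columns, got {rows.shape[1]}")
    return MarkerPanel(
        tuple(rows[1]),
        tuple(rows[0]),
        tuple(int(p) for p in rows[3]),
        tuple(rows[4]),
        tuple(rows[5]),
    )


def _read_fam(path: Path) -> Pedigree:
    rows = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    table = pd.DataFrame(
        {
            "id": rows[1],
            "sire": rows[2].where(rows[2] != "0"),
            "dam": rows[3].where(rows[3] != "0"),
            "sex": rows[4].map(_code_to_sex),
        }
    )
    return Pedigree(table)


def read_plink(path_prefix: str | os.PathLike, dialect: str = "bed_bim_fam"):
    """Read a PLINK fileset -> (MarkerPanel, Pedigree, GenotypeMatrix)."""
    prefix = Path(path_prefix)
    if dialect == "bed_bim_fam":
        panel = _read_bim(prefix.with_suffix(".bim"))
        ped = _read_fam(prefix.with_suffix(".fam"))
        dosages = _read_bed(prefix.with_suffix(".bed"), len(ped.ids), len(panel))
        return panel, ped, GenotypeMatrix(ped.ids, panel, dosages)
    if dialect == "ped_map":
        panel = read_map(prefix.with_suffix(".map"))
        return _read_ped(prefix.with_suffix(".ped"), panel)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_bed(path: Path, n_ind: int, n_markers: int) -> np.ndarray:
    raw = Path(path).read_bytes()
    if raw[:3] != BED_MAGIC:
        raise PlinkFormatError(
            f"{path}: bad magic bytes at offset 0: {raw[:3].hex()} (want {BED_MAGIC.hex()})"
        )
    bytes_per_snp = (n_ind + 3) // 4
    expected = 3 + bytes_per_snp * n_markers
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{path}: truncated/overlong record: {len(raw)} bytes at byte offset "
            f"{min(len(raw), expected)}, expected {expected}"
        )
    if n_markers == 0:
        return np.zeros((n_ind, 0), dtype=np.int8)
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(n_markers, bytes_per_snp)
    # unpack 2-bit fields, low bits first
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (payload[:, :, None] >> shifts) & 0b11  # (markers, bytes, 4)
    codes = codes.reshape(n_markers, bytes_per_snp * 4)[:, :n_ind]
    return _CODE_TO_DOSAGE[codes].T.copy()


def _read_ped(path: Path, panel: MarkerPanel):
    """Read a .ped; A1 per marker is the minor observed allele (ties broken
    alphabetically), matching the PLINK 1.9 default, since .map carries no
    allele designation."""
    ids, sires, dams, sexes = [], [], [], []
    allele_rows = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * len(panel):
                raise PlinkFormatError(
                    f"{path}: row for {fields[1] if len(fields) > 1 else '?'} has "
                    f"{len(fields)} fields, expected {6 + 2 * len(panel)}"
                )
            ids.append(fields[1])
            sires.append(fields[2] if fields[2] != "0" else None)
            dams.append(fields[3] if fields[3] != "0" else None)
            sexes.append(_code_to_sex(fields[4]))
            allele_rows.append(fields[6:])
    a1, a2 = [], []
    for j in range(len(panel)):
        counts: dict[str, int] = {}
        for row in allele_rows:
            for allele in (row[2 * j], row[2 * j + 1]):
                if allele != "0":
                    counts[allele] = counts.get(allele, 0) + 1
        if len(counts) > 2:
            raise PlinkFormatError(
                f"{path}: marker {panel.marker_ids[j]} has >2 alleles"
            )
        ordered = sorted(counts, key=lambda a: (counts[a], a))
        if len(ordered) == 2:
            a1.append(ordered[0])
            a2.append(ordered[1])
        elif len(ordered) == 1:
            a1.append("0")
            a2.append(ordered[0])
        else:
            a1.append("0")
            a2.append("0")
    panel = MarkerPanel(
        panel.marker_ids, panel.chrom_ids, panel.pos_bp, tuple(a1), tuple(a2)
    )
    dosage_rows = []
    for row in allele_rows:
        dos = np.empty(len(panel), dtype=np.int8)
        for j in range(len(panel)):
            x, y = row[2 * j], row[2 * j + 1]
            if x == "0" or y == "0":
                dos[j] = -1
            else:
                dos[j] = (x == a1[j]) + (y == a1[j])
        dosage_rows.append(dos)
    ped = Pedigree(pd.DataFrame({"id": ids, "sire": sires, "dam": dams, "sex": sexes}))
    dosages = (
        np.vstack(dosage_rows) if dosage_rows else np.zeros((0, len(panel)), dtype=np.int8)
    )
    return panel, ped, GenotypeMatrix(ids, panel, dosages)


def write_plink(
    panel: MarkerPanel,
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    path_prefix: str | os.PathLike,
    dialect: str = "bed_bim_fam",
) -> None:
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if list(genotypes.ids) != list(pedigree.ids):
        raise ValidationError("genotype rows and pedigree rows disagree")
    if dialect == "bed_bim_fam":
        _write_bim(panel, prefix.with_suffix(".bim"))
        _write_fam(pedigree, prefix.with_suffix(".fam"))
        _write_bed(genotypes.dosages, prefix.with_suffix(".bed"))
    elif dialect == "ped_map":
        _write_map(panel, prefix.with_suffix(".map"))
        _write_ped(panel, pedigree, genotypes, prefix.with_suffix(".ped"))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_map(panel: MarkerPanel, path: Path) -> None:
    with open(path, "w") as fh:
        for chrom, mid, pos in zip(panel.chrom_ids, panel.marker_ids, panel.pos_bp):
            fh.write(f"{chrom}\t{mid}\t0\t{pos}\n")


def _write_bim(panel: MarkerPanel, path: Path) -> None:
    with open(path, "w") as fh:
        for chrom, mid, pos, a1, a2 in zip(
            panel.chrom_ids, panel.marker_ids, panel.pos_bp, panel.a1, panel.a2
        ):
            fh.write(f"{chrom}\t{mid}\t0\t{pos}\t{a1}\t{a2}\n")


def _write_fam(pedigree: Pedigree, path: Path) -> None:
    with open(path, "w") as fh:
        for row in pedigree.table.itertuples():
            sire = row.sire if pd.notna(row.sire) else "0"
            dam = row.dam if pd.notna(row.dam) else "0"
            fh.write(f"0\t{row.id}\t{sire}\t{dam}\t{_sex_to_code(row.sex)}\t-9\n")


def _write_ped(panel, pedigree, genotypes, path: Path) -> None:
    with open(path, "w") as fh:
        for row in pedigree.table.itertuples():
            sire = row.sire if pd.notna(row.sire) else "0"
            dam = row.dam if pd.notna(row.dam) else "0"
            fields = ["0", row.id, sire, dam, _sex_to_code(row.sex), "-9"]
            dos = genotypes.row(row.id)
            for j, d in enumerate(dos):
                if d < 0:
                    fields += ["0", "0"]
                elif d == 2:
                    fields += [panel.a1[j], panel.a1[j]]
                elif d == 1:
                    fields += [panel.a1[j], panel.a2[j]]
                else:
                    fields += [panel.a2[j], panel.a2[j]]
            fh.write(" ".join(map(str, fields)) + "\n")


def _write_bed(dosages: np.ndarray, path: Path) -> None:
    n_ind, n_markers = dosages.shape
    bytes_per_snp = (n_ind + 3) // 4
    codes = np.empty((n_markers, bytes_per_snp * 4), dtype=np.uint8)
    codes.fill(0b00)  # zero-pad trailing slots
    lut = np.zeros(4, dtype=np.uint8)
    for d, c in _DOSAGE_TO_CODE.items():
        lut[d + 1] = c  # index by dosage+1 so missing (-1) -> 0
    codes[:, :n_ind] = lut[(dosages.T + 1)]
    codes = codes.reshape(n_markers, bytes_per_snp, 4)
    packed = (
        codes[:, :, 0] | (codes[:, :, 1] << 2) | (codes[:, :, 2] << 4) | (codes[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(BED_MAGIC)
        fh.write(packed.tobytes())
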