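"""Genotype and phenotype containers plus readers/writers for standard formats.

Genotypes are held as minor-allele dosage matrices (subjects x SNPs, values in
{0, 1, 2, MISSING}) and can be read from / written to PLINK text (.ped/.map),
PLINK binary (.bed/.bim/.fam) and VCF v4.2 (GT field only).  Phenotypes are a
long-format table keyed by (subject, drug, outcome, visit time) with optional
covariate columns; self-reported ethnicity travels as three 0/1 indicator
columns (European American, African American, Hispanic).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.  Never a valid dosage.
MISSING: int = -1

#: Per-subject 0/1 indicator columns used for self-reported ethnicity.
ETHNICITY_COLUMNS: tuple[str, ...] = ("eth_european", "eth_african", "eth_hispanic")

PHENOTYPE_KEY: tuple[str, ...] = ("subject", "drug", "outcome", "time")
PHENOTYPE_REQUIRED: tuple[str, ...] = PHENOTYPE_KEY + ("value",)


class GenotypeParseError(ValueError):
    """A genotype file does not parse under the named standard."""


class PhenotypeSchemaError(ValueError):
    """A phenotype table violates the required schema."""


@dataclass
class GenotypePanel:
    """Subjects x SNPs minor-allele dosage matrix with marker metadata.

    ``alleles[m] = (ref, alt)`` where ``alt`` is the allele counted by the
    dosage in ``calls[:, m]``.  Readers orient dosages to the minor allele of
    the loaded sample (frequency ties broken toward the alphabetically first
    allele), so downstream similarity and loading computations see a
    consistent coding.
    """

    subject_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    alleles: list[tuple[str, str]]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.validate()

    # -- structure -------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def validate(self) -> None:
        if self.calls.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snp_ids)} SNPs"
            )
        if len(self.snp_ids) != len(set(self.snp_ids)):
            raise ValueError("snp_ids are not unique")
        if len(self.chrom) != self.n_snps or len(self.pos) != self.n_snps:
            raise ValueError("chrom/pos length does not match snp count")
        if len(self.alleles) != self.n_snps:
            raise ValueError("alleles length does not match snp count")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {self.calls[i, j]} at subject "
                f"{self.subject_ids[i]}, SNP {self.snp_ids[j]}"
            )

    def is_sorted(self) -> bool:
        """True when positions are strictly increasing within each chromosome."""
        order = np.lexsort((self.pos, _chrom_sort_key(self.chrom)))
        if not np.array_equal(order, np.arange(self.n_snps)):
            return False
        same = self.chrom[1:] == self.chrom[:-1]
        return not np.any(same & (self.pos[1:] <= self.pos[:-1]))

    def sorted_by_position(self) -> "GenotypePanel":
        order = np.lexsort((self.pos, _chrom_sort_key(self.chrom)))
        return self.take_snps(order)

    def take_snps(self, index: Sequence[int] | np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(
            subject_ids=list(self.subject_ids),
            snp_ids=[self.snp_ids[i] for i in index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            alleles=[self.alleles[i] for i in index],
            calls=self.calls[:, index],
        )

    def take_subjects(self, index: Sequence[int] | np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(
            subject_ids=[self.subject_ids[i] for i in index],
            snp_ids=list(self.snp_ids),
            chrom=self.chrom,
            pos=self.pos,
            alleles=list(self.alleles),
            calls=self.calls[index, :],
        )

    # -- allele handling -------------------------------------------------
    def allele_frequency(self) -> np.ndarray:
        """Frequency of the counted (alt) allele per SNP, missing excluded."""
        calls = self.calls.astype(float)
        calls[self.calls == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(calls, axis=0) / 2.0

    def canonicalized(self) -> "GenotypePanel":
        """Reorient each SNP so the counted allele is the sample minor allele.

        Frequency ties (0.5) are broken so the counted allele is the
        alphabetically first of the pair.  Similarity and MDS results are
        invariant to this flip; it exists so that write->read round-trips are
        the identity and proxy weights are reproducible.
        """
        freq = self.allele_frequency()
        calls = self.calls.copy()
        alleles = list(self.alleles)
        for m in range(self.n_snps):
            f = freq[m]
            flip = False
            if np.isfinite(f):
                if f > 0.5:
                    flip = True
                elif f == 0.5:
                    ref, alt = alleles[m]
                    flip = min(ref, alt) != alt
            if flip:
                col = calls[:, m]
                observed = col != MISSING
                col[observed] = 2 - col[observed]
                ref, alt = alleles[m]
                alleles[m] = (alt, ref)
        return replace(self, calls=calls, alleles=alleles)


def _chrom_sort_key(chrom: np.ndarray) -> np.ndarray:
    """Numeric-aware chromosome ordering (1..22 before X/Y/MT, then lexical)."""

    def key(c: str) -> float:
        try:
            return float(int(c))
        except (TypeError, ValueError):
            return {"X": 23.0, "Y": 24.0, "XY": 25.0, "MT": 26.0}.get(str(c), 100.0)

    return np.array([key(c) for c in chrom])


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeTable:
    """Long-format trial outcomes: one row per (subject, drug, outcome, visit).

    ``data`` holds at least the columns ``subject drug outcome time value``;
    any further columns are covariates.  Ethnicity indicator columns (see
    :data:`ETHNICITY_COLUMNS`), when present, must be constant within subject.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in PHENOTYPE_REQUIRED if c not in df.columns]
        if missing:
            raise PhenotypeSchemaError(f"missing required columns: {missing}")
        df = df.copy()
        df["subject"] = df["subject"].astype(str)
        df["drug"] = df["drug"].astype(str)
        df["outcome"] = df["outcome"].astype(str)
        df["time"] = pd.to_numeric(df["time"], errors="raise")
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        if (df["time"] < 0).any():
            bad = df.loc[df["time"] < 0].iloc[0]
            raise PhenotypeSchemaError(
                f"negative visit time {bad['time']} for subject {bad['subject']}"
            )
        dup = df.duplicated(subset=list(PHENOTYPE_KEY))
        if dup.any():
            bad = df.loc[dup].iloc[0]
            raise PhenotypeSchemaError(
                "duplicate (subject, drug, outcome, time) row: "
                f"{tuple(bad[list(PHENOTYPE_KEY)])}"
            )
        for col in df.columns.difference(PHENOTYPE_REQUIRED):
            converted = pd.to_numeric(df[col], errors="coerce")
            if converted.notna().all() or (
                converted.isna() == df[col].isna()
            ).all():
                df[col] = converted
        for col in ETHNICITY_COLUMNS:
            if col in df.columns:
                vals = df[col].dropna()
                if not vals.isin((0, 1)).all():
                    raise PhenotypeSchemaError(f"{col} must be a 0/1 indicator")
                per_subject = df.groupby("subject")[col].nunique()
                if (per_subject > 1).any():
                    subj = per_subject.index[per_subject > 1][0]
                    raise PhenotypeSchemaError(
                        f"{col} varies within subject {subj}"
                    )
        # canonical internal sort: reader output independent of on-disk order
        df = df.sort_values(list(PHENOTYPE_KEY), kind="mergesort").reset_index(
            drop=True
        )
        self.data = df

    @property
    def covariate_columns(self) -> list[str]:
        extra = [c for c in self.data.columns if c not in PHENOTYPE_REQUIRED]
        return [c for c in extra if c not in ETHNICITY_COLUMNS]

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.data["subject"]))

    def ethnicity(self) -> pd.DataFrame:
        """Per-subject ethnicity indicators (empty frame when absent)."""
        cols = [c for c in ETHNICITY_COLUMNS if c in self.data.columns]
        if not cols:
            return pd.DataFrame(index=pd.Index(self.subjects, name="subject"))
        eth = (
            self.data[["subject", *cols]]
            .drop_duplicates("subject")
            .set_index("subject")
        )
        return eth.astype(float)

    def combination(self, drug: str, outcome: str) -> pd.DataFrame:
        sel = (self.data["drug"] == drug) & (self.data["outcome"] == outcome)
        return self.data.loc[sel].reset_index(drop=True)

    def combinations(self) -> list[tuple[str, str]]:
        pairs = self.data[["drug", "outcome"]].drop_duplicates()
        return [tuple(r) for r in pairs.itertuples(index=False)]


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a phenotype TSV with header ``subject drug outcome time value ...``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return PhenotypeTable(df)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotype readers/writers
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, format: str) -> GenotypePanel:
    """Read genotypes in one of ``plink-text``, ``plink-bed`` or ``vcf``.

    The returned panel codes dosages as counts of the sample minor allele;
    missing calls are preserved as :data:`MISSING`.
    """
    readers = {
        "plink-text": _read_plink_text,
        "plink-bed": _read_plink_bed,
        "vcf": _read_vcf,
    }
    if format not in readers:
        raise ValueError(f"unknown genotype format {format!r}; use one of {sorted(readers)}")
    return readers[format](Path(path)).canonicalized()


def write_genotypes(panel: GenotypePanel, path: str | Path, format: str) -> None:
    writers = {
        "plink-text": _write_plink_text,
        "plink-bed": _write_plink_bed,
        "vcf": _write_vcf,
    }
    if format not in writers:
        raise ValueError(f"unknown genotype format {format!r}; use one of {sorted(writers)}")
    writers[format](panel, Path(path))


# -- PLINK text (.ped/.map) -------------------------------------------------


def _strip_plink_prefix(path: Path, exts: tuple[str, ...]) -> Path:
    return path.with_suffix("") if path.suffix in exts else path


def _read_map(map_path: Path) -> tuple[list[str], np.ndarray, np.ndarray]:
    snp_ids: list[str] = []
    chrom: list[str] = []
    pos: list[int] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise GenotypeParseError(
                    f"{map_path}:{lineno}: expected 4 fields, got {len(fields)}"
                )
            chrom.append(fields[0])
            snp_ids.append(fields[1])
            try:
                pos.append(int(fields[3]))
            except ValueError as exc:
                raise GenotypeParseError(
                    f"{map_path}:{lineno}: non-integer position {fields[3]!r}"
                ) from exc
    return snp_ids, np.array(chrom, dtype=object), np.array(pos, dtype=np.int64)


def _read_plink_text(path: Path) -> GenotypePanel:
    prefix = _strip_plink_prefix(path, (".ped", ".map"))
    snp_ids, chrom, pos = _read_map(prefix.with_suffix(".map"))
    n_snps = len(snp_ids)
    subject_ids: list[str] = []
    allele_pairs: list[list[tuple[str, str]]] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise GenotypeParseError(
                    f"{prefix.with_suffix('.ped')}:{lineno}: expected "
                    f"{6 + 2 * n_snps} fields for {n_snps} SNPs, got {len(fields)}"
                )
            subject_ids.append(fields[1])
            allele_pairs.append(
                [(fields[6 + 2 * m], fields[7 + 2 * m]) for m in range(n_snps)]
            )
    if not subject_ids:
        raise GenotypeParseError(f"{prefix.with_suffix('.ped')}: no subjects")
    calls = np.full((len(subject_ids), n_snps), MISSING, dtype=np.int8)
    alleles: list[tuple[str, str]] = []
    for m in range(n_snps):
        observed = sorted(
            {a for row in allele_pairs for a in row[m] if a != "0"}
        )
        if len(observed) > 2:
            raise GenotypeParseError(
                f"SNP {snp_ids[m]}: more than two alleles observed {observed}"
            )
        if len(observed) == 0:
            alleles.append(("0", "0"))
            continue
        ref = observed[0]
        alt = observed[1] if len(observed) == 2 else "0"
        alleles.append((ref, alt))
        for i, row in enumerate(allele_pairs):
            a, b = row[m]
            if a == "0" or b == "0":
                continue
            calls[i, m] = (a == alt) + (b == alt)
    return GenotypePanel(subject_ids, snp_ids, chrom, pos, alleles, calls)


def _write_plink_text(panel: GenotypePanel, path: Path) -> None:
    prefix = _strip_plink_prefix(path, (".ped", ".map"))
    with open(prefix.with_suffix(".map"), "w") as fh:
        for m in range(panel.n_snps):
            fh.write(
                f"{panel.chrom[m]}\t{panel.snp_ids[m]}\t0\t{panel.pos[m]}\n"
            )
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, sid in enumerate(panel.subject_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for m in range(panel.n_snps):
                ref, alt = panel.alleles[m]
                g = panel.calls[i, m]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [ref, ref]
                elif g == 1:
                    fields += [ref, alt]
                else:
                    fields += [alt, alt]
            fh.write(" ".join(fields) + "\n")


# -- PLINK binary (.bed/.bim/.fam) ------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major mode
# 2-bit codes, counted allele is bim A1: 00=hom A1, 01=missing, 10=het, 11=hom A2
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def _read_plink_bed(path: Path) -> GenotypePanel:
    prefix = _strip_plink_prefix(path, (".bed", ".bim", ".fam"))
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype=str,
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None, dtype=str)
    subject_ids = list(fam[1])
    n, m = len(subject_ids), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise GenotypeParseError(
            f"{prefix.with_suffix('.bed')}: bad magic bytes (not SNP-major PLINK bed)"
        )
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * m:
        raise GenotypeParseError(
            f"{prefix.with_suffix('.bed')}: {body.size} data bytes, expected "
            f"{bytes_per_snp * m} for {n} subjects x {m} SNPs"
        )
    blocks = body.reshape(m, bytes_per_snp)
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    calls = _BED_DECODE[codes[:, :n]].T
    alleles = [(a2, a1) for a1, a2 in zip(bim["a1"], bim["a2"])]
    return GenotypePanel(
        subject_ids,
        list(bim["snp"]),
        bim["chrom"].to_numpy(dtype=object),
        bim["pos"].astype(np.int64).to_numpy(),
        alleles,
        calls,
    )


def _write_plink_bed(panel: GenotypePanel, path: Path) -> None:
    prefix = _strip_plink_prefix(path, (".bed", ".bim", ".fam"))
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for m in range(panel.n_snps):
            ref, alt = panel.alleles[m]
            fh.write(
                f"{panel.chrom[m]}\t{panel.snp_ids[m]}\t0\t{panel.pos[m]}"
                f"\t{alt}\t{ref}\n"
            )
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in panel.subject_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    n = panel.n_subjects
    bytes_per_snp = (n + 3) // 4
    encode = np.zeros(256, dtype=np.uint8)
    for dosage, code in _BED_ENCODE.items():
        encode[np.int8(dosage).view(np.uint8)] = code
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        for m in range(panel.n_snps):
            codes = encode[panel.calls[:, m].view(np.uint8)]
            padded = np.zeros(bytes_per_snp * 4, dtype=np.uint8)
            padded[:n] = codes
            packed = (
                padded[0::4]
                | (padded[1::4] << 2)
                | (padded[2::4] << 4)
                | (padded[3::4] << 6)
            )
            fh.write(packed.tobytes())


# -- VCF ---------------------------------------------------------------------


def _read_vcf(path: Path) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    subject_ids = list(vcf.samples)
    snp_ids: list[str] = []
    chrom: list[str] = []
    pos: list[int] = []
    alleles: list[tuple[str, str]] = []
    columns: list[np.ndarray] = []
    for record in vcf:
        if len(record.ALT) != 1:
            raise GenotypeParseError(
                f"{path}: record {record.CHROM}:{record.POS} is not biallelic"
            )
        snp_ids.append(record.ID or f"{record.CHROM}:{record.POS}")
        chrom.append(record.CHROM)
        pos.append(record.POS)
        alleles.append((record.REF, record.ALT[0]))
        # gts012: 0/1/2 = alt-allele count, 3 = unknown
        gt = np.asarray(record.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        columns.append(gt)
    if not columns:
        raise GenotypeParseError(f"{path}: no variant records")
    calls = np.stack(columns, axis=1)
    return GenotypePanel(
        subject_ids,
        snp_ids,
        np.array(chrom, dtype=object),
        np.array(pos, dtype=np.int64),
        alleles,
        calls,
    )


_VCF_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(panel: GenotypePanel, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(panel.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.subject_ids)
            + "\n"
        )
        for m in range(panel.n_snps):
            ref, alt = panel.alleles[m]
            gts = "\t".join(_VCF_GT[int(g)] for g in panel.calls[:, m])
            fh.write(
                f"{panel.chrom[m]}\t{panel.pos[m]}\t{panel.snp_ids[m]}"
                f"\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Config / logging plumbing
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def setup_logging(level: int = logging.INFO) -> None:
    """Structured log lines to stderr: ``time level module message``."""
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(levelname)s %(name)s %(message)s",
        force=True,
    )
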