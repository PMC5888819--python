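"""Readers and writers for paired-study bundles and packaged reference tables.

A *study bundle* is a directory of plain-text files:

``mrna_counts.tsv``
    genes x samples integer count matrix (first column ``gene``).
``mirna_signals.tsv``
    miRNAs x samples real-valued signal matrix (first column ``mirna``).
``metadata.tsv``
    one row per sample: ``sample, subject, tissue, age, sex, site,
    msi_status, total_pc_counts`` where ``total_pc_counts`` is the sample's
    total protein-coding read count used as the model offset.
``utrs.fasta``
    3'UTR sequences (DNA); record ids carry gene identifiers, optionally as
    ``GENE|transcript`` for multiple isoforms per gene.
``mirnas.fasta``
    mature miRNA sequences (RNA).

The packaged reference tables are machine-readable transcriptions of the
original study's published summary tables for a 217-pair colorectal
tumor/normal cohort: cohort description, dysregulated genes of the MAPK
signaling pathway, miRNA:mRNA association results, and the per-miRNA
seed-match summary. They are integrity-checked against recorded SHA-256
digests at load time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, IntegrityError, PairingError

SEX_CODES = {
    "m": "M", "male": "M",
    "f": "F", "female": "F",
}
TISSUE_CODES = {
    "tumor": "tumor", "tumour": "tumor", "carcinoma": "tumor", "t": "tumor",
    "normal": "normal", "mucosa": "normal", "normal mucosa": "normal", "n": "normal",
}
MSI_CODES = {
    "msi": "MSI", "mss": "MSS",
    "unknown": "unknown", "na": "unknown", "": "unknown", "nan": "unknown",
}

METADATA_COLUMNS = [
    "sample", "subject", "tissue", "age", "sex", "site", "msi_status",
    "total_pc_counts",
]


def normalize_sex(value: str) -> str:
    try:
        return SEX_CODES[str(value).strip().lower()]
    except KeyError:
        raise FormatError(f"unrecognized sex code: {value!r}") from None


def normalize_tissue(value: str) -> str:
    try:
        return TISSUE_CODES[str(value).strip().lower()]
    except KeyError:
        raise FormatError(f"unrecognized tissue label: {value!r}") from None


def normalize_msi(value: str) -> str:
    try:
        return MSI_CODES[str(value).strip().lower()]
    except KeyError:
        raise FormatError(f"unrecognized MSI status: {value!r}") from None


@dataclass
class PairedStudy:
    """A paired tumor/normal expression study.

    Attributes
    ----------
    subjects : DataFrame indexed by subject id with columns
        ``age`` (years), ``sex`` ({M, F}), ``site``, ``msi_status``
        ({MSI, MSS, unknown}).
    mrna_counts : DataFrame, genes x samples, non-negative integers.
    mirna_signals : DataFrame, miRNAs x samples, non-negative reals.
    sample_map : DataFrame indexed by sample id with columns ``subject``
        and ``tissue`` ({tumor, normal}).
    total_pc_counts : Series, sample id -> total protein-coding count
        (the exposure whose log is the offset of the count model).
    """

    subjects: pd.DataFrame
    mrna_counts: pd.DataFrame
    mirna_signals: pd.DataFrame
    sample_map: pd.DataFrame
    total_pc_counts: pd.Series

    def validate(self) -> "PairedStudy":
        if self.mrna_counts.index.has_duplicates:
            raise FormatError("duplicate gene identifiers in mRNA counts")
        if self.mirna_signals.index.has_duplicates:
            raise FormatError("duplicate miRNA identifiers in signal matrix")
        if (self.mrna_counts.to_numpy() < 0).any():
            raise FormatError("negative mRNA counts")
        if (self.mirna_signals.to_numpy() < 0).any():
            raise FormatError("negative miRNA signals")
        if (self.total_pc_counts <= 0).any():
            bad = self.total_pc_counts.index[self.total_pc_counts <= 0].tolist()
            raise FormatError(f"non-positive protein-coding totals for samples {bad}")
        unpaired = []
        for subject, grp in self.sample_map.groupby("subject", sort=False):
            tissues = sorted(grp["tissue"])
            if tissues != ["normal", "tumor"]:
                unpaired.append(str(subject))
        if unpaired:
            raise PairingError(
                "subjects without exactly one tumor and one normal sample: "
                + ", ".join(unpaired)
            )
        missing = set(self.sample_map.index) - set(self.mrna_counts.columns)
        if missing:
            raise FormatError(f"samples missing from mRNA counts: {sorted(missing)}")
        missing = set(self.sample_map.index) - set(self.mirna_signals.columns)
        if missing:
            raise FormatError(f"samples missing from miRNA signals: {sorted(missing)}")
        missing = set(self.sample_map.index) - set(self.total_pc_counts.index)
        if missing:
            raise FormatError(f"samples missing protein-coding totals: {sorted(missing)}")
        return self

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects.index)

    def samples_for(self, tissue: str) -> pd.Index:
        return self.sample_map.index[self.sample_map["tissue"] == tissue]

    def sample_of(self, subject: str, tissue: str) -> str:
        sel = self.sample_map[
            (self.sample_map["subject"] == subject) & (self.sample_map["tissue"] == tissue)
        ]
        if len(sel) != 1:
            raise PairingError(f"subject {subject} lacks a unique {tissue} sample")
        return sel.index[0]

    def restrict_subjects(self, subject_ids) -> "PairedStudy":
        """Return the sub-study containing only ``subject_ids`` (order kept)."""
        subject_ids = [s for s in self.subjects.index if s in set(subject_ids)]
        smap = self.sample_map[self.sample_map["subject"].isin(subject_ids)]
        samples = smap.index
        return PairedStudy(
            subjects=self.subjects.loc[subject_ids],
            mrna_counts=self.mrna_counts[samples],
            mirna_signals=self.mirna_signals[samples],
            sample_map=smap,
            total_pc_counts=self.total_pc_counts[samples],
        ).validate()


def write_study(study: PairedStudy, bundle_path,
                utrs: dict[str, str] | None = None,
                mirna_seqs: dict[str, str] | None = None) -> Path:
    """Write a study (and optional sequence sets) as a bundle directory."""
    bundle = Path(bundle_path)
    bundle.mkdir(parents=True, exist_ok=True)
    study.mrna_counts.rename_axis("gene").to_csv(bundle / "mrna_counts.tsv", sep="\t")
    study.mirna_signals.rename_axis("mirna").to_csv(bundle / "mirna_signals.tsv", sep="\t")
    meta = study.sample_map.copy()
    meta.insert(2, "age", study.subjects.loc[meta["subject"], "age"].to_numpy())
    meta.insert(3, "sex", study.subjects.loc[meta["subject"], "sex"].to_numpy())
    meta.insert(4, "site", study.subjects.loc[meta["subject"], "site"].to_numpy())
    meta.insert(5, "msi_status", study.subjects.loc[meta["subject"], "msi_status"].to_numpy())
    meta["total_pc_counts"] = study.total_pc_counts[meta.index].to_numpy()
    meta.rename_axis("sample").to_csv(bundle / "metadata.tsv", sep="\t")
    if utrs is not None:
        write_fasta(utrs, bundle / "utrs.fasta")
    if mirna_seqs is not None:
        write_fasta(mirna_seqs, bundle / "mirnas.fasta")
    return bundle


def read_study(bundle_path) -> PairedStudy:
    """Read and validate a study bundle written by :func:`write_study`."""
    bundle = Path(bundle_path)
    for name in ("mrna_counts.tsv", "mirna_signals.tsv", "metadata.tsv"):
        if not (bundle / name).exists():
            raise FormatError(f"study bundle is missing {name}")
    counts = pd.read_csv(bundle / "mrna_counts.tsv", sep="\t", index_col=0)
    if not np.issubdtype(counts.to_numpy().dtype, np.number):
        raise FormatError("mRNA count matrix contains non-numeric entries")
    if (counts.to_numpy() < 0).any():
        raise FormatError("negative mRNA counts")
    counts = counts.round().astype(np.int64)
    signals = pd.read_csv(bundle / "mirna_signals.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(bundle / "metadata.tsv", sep="\t", dtype={"sample": str, "subject": str})
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise FormatError(f"metadata is missing columns {sorted(missing_cols)}")
    meta = meta.set_index("sample")
    meta["tissue"] = meta["tissue"].map(normalize_tissue)
    meta["sex"] = meta["sex"].map(normalize_sex)
    meta["msi_status"] = meta["msi_status"].map(normalize_msi)
    subjects = (
        meta.groupby("subject", sort=False)[["age", "sex", "site", "msi_status"]]
        .first()
    )
    study = PairedStudy(
        subjects=subjects,
        mrna_counts=counts,
        mirna_signals=signals,
        sample_map=meta[["subject", "tissue"]],
        total_pc_counts=meta["total_pc_counts"].astype(np.int64),
    )
    return study.validate()


def read_fasta(path, rna: bool = False) -> dict[str, str]:
    """Read a FASTA file into ``{record id: uppercase sequence}``.

    With ``rna=True`` any T is rewritten to U (mature miRNA convention);
    otherwise U is rewritten to T (genomic/UTR convention).
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        s = s.replace("T", "U") if rna else s.replace("U", "T")
        if rec.id in seqs:
            raise FormatError(f"duplicate FASTA record id {rec.id}")
        seqs[rec.id] = s
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def utrs_by_gene(utr_seqs: dict[str, str]) -> dict[str, list[str]]:
    """Group UTR records by gene; ids may be ``GENE`` or ``GENE|transcript``."""
    grouped: dict[str, list[str]] = {}
    for name, seq in utr_seqs.items():
        gene = name.split("|", 1)[0]
        grouped.setdefault(gene, []).append(seq)
    return grouped


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------

_FIXTURE_FILES = {
    "table1": "table1_cohort.tsv",
    "table2": "table2_differential_expression.tsv",
    "table3": "table3_associations.tsv",
    "table4": "table4_seed_summary.tsv",
    "subgroup_only": "subgroup_only_genes.tsv",
}


def _parse_printed_p(value: str) -> float:
    """Parse a printed p value such as ``4.27E-30``, ``.0407`` or ``<.0001``.

    A censored value ``<x`` is parsed as its bound ``x``.
    """
    text = str(value).strip().lstrip("<")
    return float(text)


@dataclass
class ReferenceTables:
    """Machine-readable copies of the reference study's printed tables."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    subgroup_only: pd.DataFrame = field(repr=False, default=None)


def _fixture_bytes(filename: str) -> bytes:
    return resources.files("mirpair.fixtures").joinpath(filename).read_bytes()


def load_reference_tables(verify: bool = True) -> ReferenceTables:
    """Load the packaged reference tables, verifying SHA-256 checksums.

    Numeric columns are parsed; the printed forms of the p values and betas
    (which carry the tables' display precision, e.g. ``<.0001``) are kept in
    ``*_str`` companions.
    """
    if verify:
        recorded = json.loads(_fixture_bytes("checksums.json"))
        for key, filename in _FIXTURE_FILES.items():
            digest = hashlib.sha256(_fixture_bytes(filename)).hexdigest()
            if digest != recorded[filename]:
                raise IntegrityError(f"fixture {filename} fails its checksum")

    def read(key):
        import io as _io
        return pd.read_csv(_io.BytesIO(_fixture_bytes(_FIXTURE_FILES[key])), sep="\t")

    table1 = read("table1")
    table2 = read("table2")
    for col in ("p_value", "p_adjusted"):
        table2[col + "_str"] = table2[col].astype(str)
        table2[col] = table2[col].map(_parse_printed_p)
    table3 = read("table3")
    for col in ("beta", "p_raw", "p_fdr"):
        table3[col + "_str"] = table3[col].astype(str)
        table3[col] = table3[col].map(_parse_printed_p)
    table3["seed_match"] = table3["seed_match"].astype(bool)
    table4 = read("table4")
    for col in ("with_match", "without_match"):
        if col not in table4.columns:
            table4[col] = ""
        table4[col] = table4[col].fillna("").map(
            lambda s: [g for g in str(s).split(";") if g]
        )
    subgroup_only = read("subgroup_only")
    return ReferenceTables(table1=table1, table2=table2, table3=table3,
                         table4=table4, subgroup_only=subgroup_only)
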