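"""Genotype and sample-metadata I/O.

Genotypes travel as a :class:`GenotypeMatrix`: a samples x loci matrix of
A1-allele dosages (0, 1, 2, or missing) plus per-locus map information.
The on-disk format is plain-text PLINK PED/MAP; sample metadata is a
tab-separated table with geographic coordinates and grouping labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype in the dosage matrix.
MISSING: int = -1

#: Required columns of a sample-metadata table, in header order.
SAMPLE_COLUMNS = ("sample_id", "lat", "lon", "province", "region", "platform", "status")

_VALID_STATUS = frozenset({"case", "control", "unknown"})


class GenotypeFormatError(ValueError):
    """Raised when a PED/MAP or metadata file violates its format contract."""


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes as dosages of the A1 allele.

    Parameters
    ----------
    sample_ids
        Ordered, unique sample identifiers (length n).
    locus_ids
        Ordered, unique locus identifiers (length L).
    chrom
        Per-locus chromosome labels (length L).
    pos_bp
        Per-locus 1-based base-pair positions, non-negative.
    alleles
        Per-locus ``(A1, A2)`` allele characters, shape (L, 2).
    dosage
        ``(n, L)`` int8 array with entries in {0, 1, 2, MISSING},
        counting copies of A1.
    """

    sample_ids: np.ndarray
    locus_ids: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    alleles: np.ndarray
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.validate()

    # -- contracts ---------------------------------------------------------

    def validate(self) -> None:
        n, L = self.dosage.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} dosage rows")
        if len(self.locus_ids) != L:
            raise ValueError(f"{len(self.locus_ids)} locus ids for {L} dosage columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.locus_ids)) != L:
            raise ValueError("duplicate locus ids")
        if len(self.chrom) != L or len(self.pos_bp) != L or self.alleles.shape != (L, 2):
            raise ValueError("per-locus metadata length mismatch")
        if np.any(self.pos_bp < 0):
            raise ValueError("negative base-pair position")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage entries outside {0, 1, 2, MISSING}")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def sample_call_rate(self) -> np.ndarray:
        """Fraction of non-missing genotypes per sample."""
        return 1.0 - self.missing_mask().mean(axis=1)

    def locus_call_rate(self) -> np.ndarray:
        """Fraction of non-missing genotypes per locus."""
        return 1.0 - self.missing_mask().mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Per-locus frequency of A1 among non-missing allele copies.

        Loci missing in every sample get NaN.
        """
        d = self.dosage.astype(float)
        ok = self.dosage != MISSING
        d[~ok] = 0.0
        n_alleles = 2.0 * ok.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, d.sum(axis=0) / n_alleles, np.nan)

    def minor_allele_freq(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    # -- subsetting --------------------------------------------------------

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self, sample_ids=self.sample_ids[index], dosage=self.dosage[index, :]
        )

    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            locus_ids=self.locus_ids[index],
            chrom=self.chrom[index],
            pos_bp=self.pos_bp[index],
            alleles=self.alleles[index, :],
            dosage=self.dosage[:, index],
        )

    def select_samples(self, ids) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = np.array([pos[s] for s in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"sample id not in matrix: {e.args[0]!r}") from None
        return self.take_samples(idx)

    def select_loci(self, ids) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.locus_ids)}
        idx = np.array([pos[s] for s in ids], dtype=int)
        return self.take_loci(idx)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.sample_ids.copy(),
            self.locus_ids.copy(),
            self.chrom.copy(),
            self.pos_bp.copy(),
            self.alleles.copy(),
            self.dosage.copy(),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.sample_ids, other.sample_ids)
            and np.array_equal(self.locus_ids, other.locus_ids)
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos_bp, other.pos_bp)
            and np.array_equal(self.alleles, other.alleles)
            and np.array_equal(self.dosage, other.dosage)
        )


# ---------------------------------------------------------------------------
# PED / MAP
# ---------------------------------------------------------------------------


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read a PLINK text PED/MAP pair into a :class:`GenotypeMatrix`.

    The A1 allele of each locus is the first non-missing allele encountered
    reading the PED top to bottom, with a lexicographic tie-break when the
    first genotype is heterozygous; "0 0" encodes a missing genotype.
    """
    map_df = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "locus_id", "cm", "pos_bp"],
        dtype={"chrom": str, "locus_id": str},
    )
    if map_df.shape[1] != 4:
        raise GenotypeFormatError(f"{map_path}: expected 4 columns in MAP")
    if map_df["locus_id"].duplicated().any():
        dup = map_df["locus_id"][map_df["locus_id"].duplicated()].iloc[0]
        raise GenotypeFormatError(f"{map_path}: duplicate locus id {dup!r}")
    L = len(map_df)

    sample_ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * L:
                raise GenotypeFormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * L} fields, got {len(fields)}"
                )
            sid = fields[1]
            if sid in sample_ids:
                raise GenotypeFormatError(f"{ped_path}:{lineno}: duplicate sample id {sid!r}")
            sample_ids.append(sid)
            allele_rows.append(np.array(fields[6:], dtype=object))
    if not allele_rows:
        raise GenotypeFormatError(f"{ped_path}: no samples")

    al = np.stack(allele_rows)  # (n, 2L)
    a_first = al[:, 0::2]
    a_second = al[:, 1::2]
    n = len(sample_ids)

    dosage = np.full((n, L), MISSING, dtype=np.int8)
    alleles = np.empty((L, 2), dtype=object)
    for j in range(L):
        f, s = a_first[:, j], a_second[:, j]
        obs = np.where((f != "0") & (s != "0"))[0]
        uniq = sorted(set(f[obs]) | set(s[obs]))
        if len(uniq) > 2:
            raise GenotypeFormatError(
                f"locus {map_df['locus_id'][j]!r}: more than two alleles {uniq}"
            )
        if not uniq:  # all-missing locus: keep placeholder alleles
            alleles[j] = ("0", "0")
            continue
        # A1 = first allele observed; lexicographic tie-break if the first
        # non-missing genotype is heterozygous.
        i0 = obs[0]
        first_pair = sorted({f[i0], s[i0]})
        a1 = first_pair[0]
        others = [u for u in uniq if u != a1]
        a2 = others[0] if others else "0"
        alleles[j] = (a1, a2)
        dosage[obs, j] = (f[obs] == a1).astype(np.int8) + (s[obs] == a1).astype(np.int8)

    return GenotypeMatrix(
        sample_ids=np.array(sample_ids, dtype=object),
        locus_ids=map_df["locus_id"].to_numpy(dtype=object),
        chrom=map_df["chrom"].to_numpy(dtype=object),
        pos_bp=map_df["pos_bp"].to_numpy(),
        alleles=alleles,
        dosage=dosage,
    )


def write_ped_map(G: GenotypeMatrix, out_prefix) -> tuple[str, str]:
    """Write ``G`` as ``<out_prefix>.ped`` / ``<out_prefix>.map``.

    Missing genotypes are written as "0 0". Returns the two file paths.
    """
    if G.n_loci == 0 or G.n_samples == 0:
        raise ValueError("refusing to write an empty genotype matrix")
    ped_path = f"{out_prefix}.ped"
    map_path = f"{out_prefix}.map"
    with open(map_path, "w") as fh:
        for c, lid, bp in zip(G.chrom, G.locus_ids, G.pos_bp):
            fh.write(f"{c}\t{lid}\t0\t{bp}\n")
    a1 = G.alleles[:, 0]
    a2 = G.alleles[:, 1]
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(G.sample_ids):
            row = G.dosage[i]
            parts = [str(sid), str(sid), "0", "0", "0", "0"]
            for j, d in enumerate(row):
                if d == MISSING:
                    parts += ["0", "0"]
                elif d == 2:
                    parts += [a1[j], a1[j]]
                elif d == 1:
                    parts += [a1[j], a2[j]]
                else:
                    parts += [a2[j], a2[j]]
            fh.write(" ".join(parts) + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


def validate_sample_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata frame in place and return it.

    Checks the schema, id uniqueness, coordinate bounds, status labels and
    that every province maps to a single region.
    """
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise GenotypeFormatError(f"metadata missing required columns: {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise GenotypeFormatError(f"duplicate sample_id {dup!r}")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    bad = df.index[lat.isna() | lon.isna() | (lat.abs() > 90) | (lon.abs() > 180)]
    if len(bad):
        raise GenotypeFormatError(
            f"invalid coordinates at rows {list(bad[:5])} (0-based data rows)"
        )
    df = df.assign(lat=lat, lon=lon)
    bad_status = set(df["status"]) - _VALID_STATUS
    if bad_status:
        raise GenotypeFormatError(f"invalid status labels: {sorted(bad_status)}")
    amb = df.groupby("province")["region"].nunique()
    if (amb > 1).any():
        raise GenotypeFormatError(
            f"provinces in multiple regions: {list(amb.index[amb > 1])}"
        )
    return df


def read_sample_metadata(tsv_path) -> pd.DataFrame:
    """Read and validate a tab-separated sample-metadata table."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    return validate_sample_table(df)


def write_sample_metadata(df: pd.DataFrame, tsv_path) -> None:
    df.to_csv(tsv_path, sep="\t", index=False)


def align_samples(G: GenotypeMatrix, S: pd.DataFrame) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Intersect genotypes and metadata on sample id.

    Unmatched samples on either side are dropped with a warning (datasets
    combined from several sources rarely overlap perfectly).
    """
    meta_ids = set(S["sample_id"])
    keep = [s for s in G.sample_ids if s in meta_ids]
    n_dropped = G.n_samples - len(keep)
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} genotyped samples without metadata")
        logger.warning("dropping %d genotyped samples without metadata", n_dropped)
    if not keep:
        raise ValueError("no samples shared between genotypes and metadata")
    G2 = G.select_samples(keep)
    S2 = S.set_index("sample_id").loc[keep].reset_index()
    return G2, S2
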