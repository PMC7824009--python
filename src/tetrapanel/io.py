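"""Data containers, file readers/writers, and SNP filtering.

The central container is :class:`DosageMatrix`: a samples x markers matrix of
allele dosages. For an autotetraploid, a dosage is the count (0-4) of the
alternate allele at a locus, i.e. the five allelic states AAAA..aaaa. A
"diploidized" matrix collapses the three tetraploid heterozygote classes
(AAAa, AAaa, Aaaa) into a single heterozygote code, giving codes 0/1/2.

Filters implemented here are the standard array-QC chain for dosage data:
per-marker missingness, probe-alignment identity, and minor allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, UndefinedStatisticError

MISSING = np.nan

#: chromosome labels used for unanchored marker groups
UNANCHORED_LABELS = ("00", "UN")


@dataclass
class DosageMatrix:
    """Allele-dosage genotype matrix (samples x markers).

    Parameters
    ----------
    sample_ids, marker_ids
        Row and column labels. Marker order follows the marker map.
    dosages
        Float array of shape (n_samples, n_markers); integer dosage values
        in ``[0, ploidy]`` with ``NaN`` for missing calls.
    ploidy
        4 for tetraploid dosages, 2 for diploidized codes.
    """

    sample_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray
    ploidy: int = 4

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise FormatError(
                f"dosage array shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.marker_ids)} markers"
            )
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise FormatError("duplicate marker ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        self._validate_values()

    def _validate_values(self):
        d = self.dosages
        observed = ~np.isnan(d)
        bad = observed & ((d < 0) | (d > self.ploidy) | (d != np.round(d)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"invalid dosage {d[i, j]!r} for marker {self.marker_ids[j]!r}, "
                f"sample {self.sample_ids[i]!r}: expected integer in "
                f"[0, {self.ploidy}] or missing"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def marker_index(self, marker_ids) -> np.ndarray:
        pos = {m: j for j, m in enumerate(self.marker_ids)}
        try:
            return np.array([pos[m] for m in marker_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"marker {e.args[0]!r} not in matrix") from None

    def subset_markers(self, marker_ids) -> "DosageMatrix":
        """Restrict to the given markers, keeping their given order."""
        idx = self.marker_index(marker_ids)
        return replace(
            self, marker_ids=list(marker_ids), dosages=self.dosages[:, idx].copy()
        )

    def subset_samples(self, sample_ids) -> "DosageMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return replace(
            self, sample_ids=list(sample_ids), dosages=self.dosages[idx, :].copy()
        )

    def missing_per_marker(self) -> np.ndarray:
        return np.isnan(self.dosages).sum(axis=0)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path, fmt: str = "dosage-csv", ploidy: int = 4,
                   dosage_field: str = "DS") -> DosageMatrix:
    """Read a dosage genotype matrix.

    ``dosage-csv``: header row of sample ids, first column marker ids, cells
    in ``{0..ploidy, NA}``, one row per marker.

    ``vcf-dosage``: VCF 4.x with a per-sample FORMAT dosage field (default
    ``DS``); values must be integral (2.0 is accepted, 1.4 is not).
    """
    if fmt == "dosage-csv":
        return _read_dosage_csv(path, ploidy)
    if fmt == "vcf-dosage":
        return _read_vcf_dosage(path, ploidy, dosage_field)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_dosage_csv(path, ploidy) -> DosageMatrix:
    df = pd.read_csv(path, index_col=0, na_values=["NA"], dtype=str,
                     keep_default_na=True)
    markers = [str(m) for m in df.index]
    samples = [str(s) for s in df.columns]
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as e:
        raise FormatError(f"non-numeric dosage in {path}: {e}") from None
    # rows are markers: transpose to samples x markers
    return DosageMatrix(samples, markers, values.T, ploidy=ploidy)


def write_genotypes(g: DosageMatrix, path, fmt: str = "dosage-csv",
                    marker_map: pd.DataFrame | None = None,
                    dosage_field: str = "DS") -> None:
    if fmt == "dosage-csv":
        df = pd.DataFrame(g.dosages.T, index=g.marker_ids, columns=g.sample_ids)
        # integer cells, NA for missing
        df = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
        df.index.name = "marker"
        df.to_csv(path)
    elif fmt == "vcf-dosage":
        _write_vcf_dosage(g, path, marker_map, dosage_field)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf_dosage(path, ploidy, dosage_field) -> DosageMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    markers, columns = [], []
    for v in vcf:
        mid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        raw = v.format(dosage_field)
        if raw is None:
            raise FormatError(f"record {mid} lacks FORMAT field {dosage_field!r}")
        vals = np.asarray(raw, dtype=float).reshape(len(samples))
        col = np.where(np.isfinite(vals) & (vals > -1), vals, np.nan)
        observed = ~np.isnan(col)
        nonint = observed & (np.abs(col - np.round(col)) > 1e-9)
        if nonint.any():
            i = int(np.flatnonzero(nonint)[0])
            raise FormatError(
                f"non-integral dosage {col[i]:g} at marker {mid!r}, "
                f"sample {samples[i]!r}"
            )
        markers.append(mid)
        columns.append(np.round(col))
    vcf.close()
    if len(set(markers)) != len(markers):
        raise FormatError("duplicate marker id in VCF")
    dosages = (np.column_stack(columns) if columns
               else np.empty((len(samples), 0)))
    return DosageMatrix(samples, markers, dosages, ploidy=ploidy)


def _write_vcf_dosage(g, path, marker_map, dosage_field):
    if marker_map is not None:
        mm = marker_map.set_index("marker")
        chrom = [str(mm.loc[m, "chrom"]) for m in g.marker_ids]
        pos = [int(mm.loc[m, "pos_bp"]) for m in g.marker_ids]
    else:
        chrom = ["1"] * g.n_markers
        pos = list(range(1, g.n_markers + 1))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f'##FORMAT=<ID={dosage_field},Number=1,Type=Float,'
                 f'Description="Alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        for j, m in enumerate(g.marker_ids):
            cells = [
                "." if np.isnan(v) else str(int(v)) for v in g.dosages[:, j]
            ]
            fh.write(f"{chrom[j]}\t{pos[j]}\t{m}\tA\tT\t.\t.\t.\t"
                     f"{dosage_field}\t" + "\t".join(cells) + "\n")


def read_marker_map(path) -> pd.DataFrame:
    """Read a marker map TSV with columns marker, chrom, pos_bp (1-based)."""
    mm = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str})
    missing = {"marker", "chrom", "pos_bp"} - set(mm.columns)
    if missing:
        raise FormatError(f"marker map lacks columns {sorted(missing)}")
    if mm["marker"].duplicated().any():
        raise FormatError("duplicate marker id in map")
    if (mm["pos_bp"] < 1).any():
        raise FormatError("marker map positions must be >= 1")
    return mm


def write_marker_map(mm: pd.DataFrame, path) -> None:
    mm.to_csv(path, sep="\t", index=False)


def read_identity_table(path) -> pd.DataFrame:
    """Read a BLAST tabular (outfmt 6) file into a best-hit identity table.

    Field 1 is the query (marker probe) id and field 3 the percent identity.
    Only the best hit (highest pident) per marker is kept; markers absent
    from the file are treated as unmapped.
    """
    cols = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
    df = pd.read_csv(path, sep="\t", names=cols, dtype={"qseqid": str},
                     comment="#")
    best = (df.sort_values("pident", ascending=False)
              .drop_duplicates("qseqid", keep="first"))
    return (best[["qseqid", "pident"]]
            .rename(columns={"qseqid": "marker"})
            .reset_index(drop=True))


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype CSV: sample_id, family, one column per trait."""
    ph = pd.read_csv(path, dtype={"sample_id": str, "family": str})
    missing = {"sample_id", "family"} - set(ph.columns)
    if missing:
        raise FormatError(f"phenotype table lacks columns {sorted(missing)}")
    return ph


def read_sample_metadata(path) -> pd.DataFrame:
    md = pd.read_csv(path, dtype=str)
    missing = {"sample_id", "family", "role"} - set(md.columns)
    if missing:
        raise FormatError(f"sample metadata lacks columns {sorted(missing)}")
    return md


# ---------------------------------------------------------------------------
# allele frequency and filters
# ---------------------------------------------------------------------------

def allele_frequency(g: DosageMatrix) -> np.ndarray:
    """Per-marker alternate-allele frequency, mean(dosage)/ploidy over
    non-missing samples."""
    n_obs = (~np.isnan(g.dosages)).sum(axis=0)
    if (n_obs == 0).any():
        bad = [g.marker_ids[j] for j in np.flatnonzero(n_obs == 0)]
        raise UndefinedStatisticError(
            f"allele frequency undefined for all-missing markers: {bad}"
        )
    return np.nanmean(g.dosages, axis=0) / g.ploidy


def maf(g: DosageMatrix) -> np.ndarray:
    """Per-marker minor allele frequency min(p, 1-p); always <= 0.5."""
    p = allele_frequency(g)
    return np.minimum(p, 1.0 - p)


def filter_missingness(g: DosageMatrix, max_missing: int = 10) -> DosageMatrix:
    """Keep markers with at most ``max_missing`` missing sample calls."""
    if max_missing < 0:
        raise ValueError("max_missing must be >= 0")
    keep = g.missing_per_marker() <= max_missing
    return g.subset_markers([m for m, k in zip(g.marker_ids, keep) if k])


def filter_identity(g: DosageMatrix, identity: pd.DataFrame,
                    min_pident: float = 97.0) -> DosageMatrix:
    """Keep markers whose probe-alignment percent identity is >= threshold.

    Markers absent from the table are dropped: an unmapped probe cannot be
    placed on a pseudomolecule and so cannot take part in windowed pruning.
    """
    ok = set(identity.loc[identity["pident"] >= min_pident, "marker"])
    return g.subset_markers([m for m in g.marker_ids if m in ok])


def filter_maf(g: DosageMatrix, min_maf: float = 0.05) -> DosageMatrix:
    """Drop markers with minor allele frequency strictly below ``min_maf``."""
    keep = maf(g) >= min_maf
    return g.subset_markers([m for m, k in zip(g.marker_ids, keep) if k])


def diploidize(g: DosageMatrix) -> DosageMatrix:
    """Collapse tetraploid dosages to diploid-style codes.

    Mapping: 0 -> 0, {1,2,3} -> 1 (single heterozygote class), 4 -> 2;
    missing stays missing. Missingness count is preserved exactly.
    """
    d = g.dosages
    out = np.full_like(d, np.nan)
    out[d == 0] = 0.0
    out[(d >= 1) & (d <= 3)] = 1.0
    out[d == 4] = 2.0
    return DosageMatrix(list(g.sample_ids), list(g.marker_ids), out, ploidy=2)
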