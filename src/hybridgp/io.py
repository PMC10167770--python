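"""File formats, configuration and run manifests.

Genotypes travel as VCF (biallelic records, inbred GT calls) or as a TSV
matrix (lines x markers, codes -1/0/+1, header row of marker IDs);
phenotypes and mating designs as CSV; square relationship matrices and
design matrices as TSV with ID headers; configuration as YAML.  The VCF
dosage convention is fixed: homozygous reference -> -1, heterozygous -> 0,
homozygous alternate -> +1, missing call -> NaN.
"""

from __future__ import annotations

import hashlib
import json
import platform
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hybrids import MatingDesign
from .markers import GenotypeMatrix
from .simdata import SimConfig
from .varcomp import validate_phenotypes

_CODE_FROM_DOSAGE = {0: -1.0, 1: 0.0, 2: 1.0}


# ---------------------------------------------------------------- genotypes

def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or the TSV matrix dialect.

    ``format`` is "vcf" or "tsv"; when omitted it is inferred from the
    file suffix.  Multi-allelic VCF records are skipped with a warning.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if ".vcf" in path.suffixes else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv_matrix(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    lines = list(vcf.samples)
    codes_cols: list[np.ndarray] = []
    markers: list[str] = []
    rows = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        col = np.empty(len(lines))
        for i, gt in enumerate(rec.genotypes):
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                col[i] = np.nan
            else:
                col[i] = _CODE_FROM_DOSAGE[int(sum(alleles))]
        marker_id = rec.ID if rec.ID not in (None, ".") \
            else f"S{rec.CHROM}_{rec.POS}"
        markers.append(marker_id)
        codes_cols.append(col)
        rows.append(
            {"chrom": str(rec.CHROM), "pos": int(rec.POS),
             "ref": rec.REF, "alt": rec.ALT[0]}
        )
    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} multi-allelic record(s) in {path.name}",
            stacklevel=2,
        )
    if not markers:
        raise ValueError(f"no biallelic records in {path}")
    marker_map = pd.DataFrame(rows, index=pd.Index(markers, name="marker"))
    return GenotypeMatrix(
        lines=lines,
        markers=markers,
        codes=np.column_stack(codes_cols),
        marker_map=marker_map,
    )


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write genotypes as uncompressed VCF 4.2 with inbred-style GT calls
    (0/0, 0/1, 1/1, ./.)."""
    path = Path(path)
    gt_of = {-1.0: "0/0", 0.0: "0/1", 1.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hybridgp\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(genotypes.marker_map["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.lines)
            + "\n"
        )
        mm = genotypes.marker_map
        for j, marker in enumerate(genotypes.markers):
            row = mm.iloc[j]
            calls = "\t".join(
                "./." if np.isnan(c) else gt_of[c]
                for c in genotypes.codes[:, j]
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{marker}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def _read_tsv_matrix(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    codes = df.to_numpy(dtype=float)
    finite = codes[~np.isnan(codes)]
    bad = set(finite) - {-1.0, 0.0, 1.0}
    if bad:
        raise ValueError(
            f"{path}: genotype codes outside {{-1, 0, +1}}: {sorted(bad)[:5]}"
        )
    markers = [str(c) for c in df.columns]
    map_path = path.with_suffix(path.suffix + ".map")
    if map_path.exists():
        marker_map = pd.read_csv(map_path, sep="\t", index_col=0,
                                 dtype={"chrom": str})
        marker_map.index = marker_map.index.astype(str)
    else:
        marker_map = pd.DataFrame(
            {"chrom": "1", "pos": np.arange(len(markers)) + 1,
             "ref": "A", "alt": "T"},
            index=pd.Index(markers, name="marker"),
        )
    return GenotypeMatrix(
        lines=[str(i) for i in df.index],
        markers=markers,
        codes=codes,
        marker_map=marker_map,
    )


def write_tsv_matrix(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write the lines x markers code matrix as TSV plus a .map sidecar."""
    path = Path(path)
    genotypes.to_frame().to_csv(path, sep="\t", index_label="line")
    genotypes.marker_map.to_csv(
        path.with_suffix(path.suffix + ".map"), sep="\t", index_label="marker"
    )


# --------------------------------------------------- phenotypes and designs

def read_phenotypes(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    return validate_phenotypes(table)


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    validate_phenotypes(table).to_csv(path, index=False)


def read_design(path: str | Path) -> MatingDesign:
    return MatingDesign(pd.read_csv(path))


def write_design(design: MatingDesign, path: str | Path) -> None:
    design.table.to_csv(path, index=False)


def write_square_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="id")


# -------------------------------------------------------- config / manifest

def read_sim_config(path: str | Path) -> SimConfig:
    """Load a SimConfig from YAML (field names mirror the dataclass)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(SimConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown simulation config key(s): {sorted(unknown)}")
    for key in ("group_sizes", "allele_freq_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SimConfig(**raw)


def write_sim_config(config: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def file_checksum(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(
    path: str | Path,
    command: str,
    seed: int | None,
    inputs: dict[str, str | Path] | None = None,
    outputs: dict[str, str | Path] | None = None,
) -> None:
    """Record versions, seed and input checksums so a run is regenerable."""
    from . import __version__

    manifest = {
        "tool": "hybridgp",
        "version": __version__,
        "command": command,
        "seed": seed,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "inputs": {
            name: {"path": str(p), "sha256": file_checksum(p)}
            for name, p in (inputs or {}).items()
        },
        "outputs": {name: str(p) for name, p in (outputs or {}).items()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
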