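"""Sampling of genotyped individuals and all dataset file formats.

Formats written by :func:`write_outputs`:

* ``genotypes.vcf`` — VCF v4.2, single contig ``1``, biallelic SNPs with
  phased GT by default (truth phase is known); 1-based POS.
* ``genotypes.ped`` / ``genotypes.map`` — plink 1.x text formats, map
  distance in cM (= 100 x map fraction), alleles coded 1/2 by default.
* ``truth_dosage.tsv`` — long format, one row per individual x SNP with
  one dosage column per source (S-agnostic).
* ``truth_tracts.tsv`` — BED-like: 0-based half-open bp intervals with
  individual, chromosome copy and source columns.
* ``samples.tsv`` — individual, population label, admixed flag.
* ``scenario.json`` / ``manifest.json`` — provenance and checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass

import numpy as np

from .errors import EmptyDatasetError, FormatError, ParameterError
from .forward import AncestryTract, PopulationSet, _as_rng

logger = logging.getLogger(__name__)


@dataclass
class SampleSet:
    """Analysis-ready dataset sampled from the forward simulation.

    ``genotypes`` has shape ``(n_individuals, M, 2)`` holding the two
    phased alleles; ``Z`` has shape ``(n_individuals, M, S)`` with true
    ancestry dosages in {0, 0.5, 1}; ``tracts`` keeps the exact ancestry
    mosaic (pair of tract tuples) for every sampled individual.
    """

    genotypes: np.ndarray
    positions: np.ndarray
    bp_positions: np.ndarray
    population_of_individual: np.ndarray
    is_admixed: np.ndarray
    Z: np.ndarray
    tracts: list[tuple[tuple[AncestryTract, ...], tuple[AncestryTract, ...]]]
    n_sources: int
    map_length_bp: int

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def validate(self) -> None:
        n, m = self.genotypes.shape[:2]
        assert self.Z.shape == (n, m, self.n_sources)
        assert np.allclose(self.Z.sum(axis=2), 1.0)
        counts = self.genotypes.sum(axis=(0, 2))
        if np.any((counts == 0) | (counts == 2 * n)):
            raise AssertionError("monomorphic column present")


def map_fraction_to_bp(positions: np.ndarray, map_length_bp: int) -> np.ndarray:
    """1-based bp coordinates ``1 + floor(pos * L)``; collisions bumped up."""
    bp = (1 + np.floor(np.asarray(positions) * map_length_bp)).astype(np.int64)
    for i in range(1, len(bp)):
        if bp[i] <= bp[i - 1]:
            bp[i] = bp[i - 1] + 1
    return bp


def sample_individuals(pops: PopulationSet, o_per_pop, rng,
                       admixed=None) -> SampleSet:
    """Sample ``o_p`` individuals per population, uniformly with replacement.

    Duplicates are permitted and ``o_p`` may exceed the population size.
    ``admixed`` flags populations whose individuals enter the accuracy
    average downstream (defaults to all False).
    """
    rng = _as_rng(rng)
    o_per_pop = np.asarray(o_per_pop, dtype=int)
    if np.any(o_per_pop < 0):
        raise ParameterError("o_per_pop must be nonnegative")
    if len(o_per_pop) != pops.n_populations:
        raise ParameterError("o_per_pop length must equal P")
    if admixed is None:
        admixed = np.zeros(pops.n_populations, dtype=bool)
    admixed = np.asarray(admixed, dtype=bool)

    positions = pops.positions
    m = len(positions)
    s = pops.n_sources
    chosen: list = []
    pop_labels: list[int] = []
    for p, o_p in enumerate(o_per_pop):
        n_p = len(pops.populations[p])
        idx = rng.integers(n_p, size=o_p)
        chosen.extend(pops.populations[p][i] for i in idx)
        pop_labels.extend([p] * int(o_p))

    n = len(chosen)
    genotypes = np.empty((n, m, 2), dtype=np.uint8)
    z = np.zeros((n, m, s), dtype=np.float32)
    tracts = []
    rows = np.arange(m)
    for i, ind in enumerate(chosen):
        for c in (0, 1):
            genotypes[i, :, c] = ind.copies[c].alleles
            z[i, rows, ind.copies[c].source_at(positions)] += 0.5
        tracts.append((ind.copies[0].tracts, ind.copies[1].tracts))

    pop_labels = np.asarray(pop_labels, dtype=int)
    return SampleSet(
        genotypes=genotypes,
        positions=positions.copy(),
        bp_positions=map_fraction_to_bp(positions, pops.map_length_bp),
        population_of_individual=pop_labels,
        is_admixed=admixed[pop_labels],
        Z=z,
        tracts=tracts,
        n_sources=s,
        map_length_bp=pops.map_length_bp,
    )


def filter_monomorphic(sample: SampleSet) -> tuple[SampleSet, np.ndarray]:
    """Drop columns monomorphic across *all* sampled alleles jointly.

    Returns the filtered sample and the strictly increasing vector of
    kept original column indices.
    """
    counts = sample.genotypes.sum(axis=(0, 2))
    keep = np.flatnonzero((counts > 0) & (counts < 2 * sample.n_individuals))
    if len(keep) == 0:
        raise EmptyDatasetError("all SNP columns are monomorphic in the sample")
    filtered = SampleSet(
        genotypes=np.ascontiguousarray(sample.genotypes[:, keep, :]),
        positions=sample.positions[keep],
        bp_positions=sample.bp_positions[keep],
        population_of_individual=sample.population_of_individual,
        is_admixed=sample.is_admixed,
        Z=np.ascontiguousarray(sample.Z[:, keep, :]),
        tracts=sample.tracts,
        n_sources=sample.n_sources,
        map_length_bp=sample.map_length_bp,
    )
    return filtered, keep


# ---------------------------------------------------------------------------
# writers


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _individual_names(sample: SampleSet) -> list[str]:
    return [f"ind{i:04d}" for i in range(sample.n_individuals)]


def write_vcf(sample: SampleSet, path: str, phased: bool = True) -> None:
    sep = "|" if phased else "/"
    names = _individual_names(sample)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mosaicsim\n")
        fh.write(f"##contig=<ID=1,length={sample.map_length_bp}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(names) + "\n")
        geno = sample.genotypes
        for j in range(sample.n_sites):
            row = "\t".join(f"{geno[i, j, 0]}{sep}{geno[i, j, 1]}"
                            for i in range(sample.n_individuals))
            fh.write(f"1\t{sample.bp_positions[j]}\tsnp{j}\tA\tT\t.\tPASS\t.\tGT\t{row}\n")


def read_vcf_genotypes(path: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read back a VCF written by :func:`write_vcf`.

    Returns ``(genotypes (n, M, 2), bp_positions, sample_names)``.
    """
    names: list[str] = []
    bp: list[int] = []
    rows: list[list[tuple[int, int]]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                names = fields[9:]
                continue
            bp.append(int(fields[1]))
            row = []
            for g in fields[9:]:
                sep = "|" if "|" in g else "/"
                a, b = g.split(sep)
                row.append((int(a), int(b)))
            rows.append(row)
    if not names:
        raise FormatError(f"{path}: missing #CHROM header")
    geno = np.array(rows, dtype=np.uint8).transpose(1, 0, 2)
    return geno, np.array(bp, dtype=np.int64), names


def write_plink(sample: SampleSet, ped_path: str, map_path: str,
                allele_coding: str = "12") -> None:
    """plink 1.x text .ped/.map; phase is necessarily lost in .ped."""
    if allele_coding == "12":
        code = ("1", "2")
    elif allele_coding.upper() == "AT":
        code = ("A", "T")
    else:
        raise ParameterError("allele_coding must be '12' or 'AT'")
    names = _individual_names(sample)
    with open(map_path, "w") as fh:
        for j in range(sample.n_sites):
            cm = 100.0 * sample.positions[j]
            fh.write(f"1\tsnp{j}\t{cm:.8f}\t{sample.bp_positions[j]}\n")
    with open(ped_path, "w") as fh:
        for i, name in enumerate(names):
            fid = f"pop{sample.population_of_individual[i]}"
            alleles = sample.genotypes[i].reshape(-1)
            geno = " ".join(code[a] for a in alleles)
            fh.write(f"{fid} {name} 0 0 0 -9 {geno}\n")


def read_plink_ped(ped_path: str, allele_coding: str = "12") -> np.ndarray:
    """Genotype allele pairs (n, M, 2) from a .ped file (unphased order)."""
    inv = {"1": 0, "2": 1} if allele_coding == "12" else {"A": 0, "T": 1}
    rows = []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            alleles = [inv[a] for a in parts[6:]]
            rows.append(alleles)
    arr = np.array(rows, dtype=np.uint8)
    return arr.reshape(arr.shape[0], -1, 2)


def write_truth_dosage(sample: SampleSet, path: str) -> None:
    header = ["individual", "snp_index"] + [f"s{k + 1}" for k in range(sample.n_sources)]
    z = sample.Z
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for i in range(sample.n_individuals):
            for j in range(sample.n_sites):
                vals = "\t".join(f"{z[i, j, k]:g}" for k in range(sample.n_sources))
                fh.write(f"{i}\t{j}\t{vals}\n")


def read_truth_dosage(path: str) -> np.ndarray:
    """Z array (n, M, S) from a truth_dosage.tsv file."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        s = len(header) - 2
        data = np.loadtxt(fh, delimiter="\t")
    if data.ndim == 1:
        data = data[None, :]
    n = int(data[:, 0].max()) + 1
    m = int(data[:, 1].max()) + 1
    z = np.zeros((n, m, s), dtype=np.float32)
    z[data[:, 0].astype(int), data[:, 1].astype(int)] = data[:, 2:]
    return z


def write_truth_tracts(sample: SampleSet, path: str) -> None:
    """BED-like tract table: 0-based half-open bp intervals."""
    L = sample.map_length_bp
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tindividual\tcopy\tsource\n")
        for i, (t0, t1) in enumerate(sample.tracts):
            for c, tl in enumerate((t0, t1)):
                for t in tl:
                    start = int(np.floor(t.start * L))
                    end = int(np.floor(t.end * L)) if t.end < 1.0 else L
                    fh.write(f"1\t{start}\t{end}\t{i}\t{c}\t{t.source + 1}\n")


def write_samples_table(sample: SampleSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("individual\tpopulation\tis_admixed\n")
        for i, name in enumerate(_individual_names(sample)):
            fh.write(
                f"{name}\tpop{sample.population_of_individual[i]}\t"
                f"{int(sample.is_admixed[i])}\n"
            )


def read_samples_table(path: str) -> tuple[list[str], np.ndarray, np.ndarray]:
    names, pops, adm = [], [], []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            a, b, c = line.split()
            names.append(a)
            pops.append(b)
            adm.append(bool(int(c)))
    return names, np.array(pops), np.array(adm, dtype=bool)


def write_outputs(sample: SampleSet, out_dir: str,
                  formats: tuple[str, ...] = ("vcf", "plink", "truth", "json"),
                  phased: bool = True, allele_coding: str = "12",
                  config: dict | None = None, seed: int | None = None) -> dict:
    """Write all requested dataset artifacts and a checksum manifest."""
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []

    def path(name: str) -> str:
        written.append(name)
        return os.path.join(out_dir, name)

    if "vcf" in formats:
        write_vcf(sample, path("genotypes.vcf"), phased=phased)
    if "plink" in formats:
        write_plink(sample, path("genotypes.ped"), path("genotypes.map"),
                    allele_coding=allele_coding)
    if "truth" in formats:
        write_truth_dosage(sample, path("truth_dosage.tsv"))
        write_truth_tracts(sample, path("truth_tracts.tsv"))
        write_samples_table(sample, path("samples.tsv"))
    if "json" in formats:
        with open(path("scenario.json"), "w") as fh:
            json.dump({"config": config or {}, "seed": seed}, fh, indent=2,
                      default=str)

    manifest = {
        "files": {
            name: _sha256(os.path.join(out_dir, name)) for name in written
        }
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_inferred_matrix(path: str, n_sources: int, n_sites: int,
                         n_individuals: int):
    """Read an externally produced local-ancestry dosage matrix.

    Layout: whitespace-delimited plain text, ``n_individuals * n_sites``
    rows in individual-major order (row ``i * n_sites + m`` is individual
    ``i`` at SNP ``m``) and ``n_sources`` columns of nonnegative ancestry
    proportions.  Rows are renormalized to sum to 1; any renormalization
    beyond 1e-6 is logged.
    """
    from .evaluation import InferredAncestry

    data = np.loadtxt(path, dtype=float, ndmin=2)
    if data.shape != (n_individuals * n_sites, n_sources):
        raise FormatError(
            f"{path}: expected shape {(n_individuals * n_sites, n_sources)}, "
            f"got {data.shape}"
        )
    if np.any(data < 0):
        raise FormatError(f"{path}: negative ancestry proportions")
    sums = data.sum(axis=1)
    if np.any(sums == 0):
        raise FormatError(f"{path}: row with zero total ancestry")
    dev = np.abs(sums - 1).max()
    if dev > 1e-6:
        logger.warning("renormalizing inferred ancestry rows (max |sum-1| = %g)", dev)
    data = data / sums[:, None]
    x = data.reshape(n_individuals, n_sites, n_sources)
    return InferredAncestry(X=x)
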