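"""File dialects: phased VCF, haplotype/effects/map TSV, crosses TSV,
metrics CSV, summary JSON, and YAML run configuration.

All tabular dialects are UTF-8, tab-separated, unquoted, with loci
ordered and 1-based in files.  The genetic map is interval-based
(``L - 1`` recombination frequencies); centimorgan positions are
converted with Haldane's no-interference map function
``r = 0.5 (1 - exp(-2 d / 100))``.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import yaml

from .core import GeneticMap, GenotypeTensor, TraitModel
from .errors import FormatError
from .meiosis import LookAheadSpec
from .optimize import MatingPlan
from .simulate import ProgramConfig

__all__ = [
    "read_phased_vcf",
    "read_haplotype_tsv",
    "write_haplotype_tsv",
    "read_effects_tsv",
    "write_effects_tsv",
    "read_map_tsv",
    "write_map_tsv",
    "write_crosses_tsv",
    "haldane_cm_to_r",
    "load_config",
    "write_summary_json",
]


def haldane_cm_to_r(d_cm: np.ndarray) -> np.ndarray:
    """Haldane map function: genetic distance in cM to recombination
    frequency, ``r = 0.5 (1 - exp(-2 d / 100))``."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


# ---------------------------------------------------------------------------
# phased VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(path: str, major_is: str = "alt") -> GenotypeTensor:
    """Read phased biallelic genotypes from a VCF.

    ``major_is`` controls allele polarity: ``alt`` (default) codes the
    ALT allele as 1, ``ref`` codes REF as 1, and ``frequency`` recodes
    so that the observed major allele at each locus is 1 (ties keep
    ALT).  Unphased, missing, or multiallelic records are rejected with
    an error naming the record.
    """
    from cyvcf2 import VCF

    if major_is not in ("alt", "ref", "frequency"):
        raise ValueError("major_is must be 'alt', 'ref' or 'frequency'")
    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF contains no samples")
    rows = []
    for variant in vcf:
        label = f"{variant.CHROM}:{variant.POS}"
        if len(variant.ALT) != 1:
            raise FormatError(f"{path}: multiallelic site at {label}")
        site = np.empty((2, len(samples)), dtype=np.uint8)
        for i, gt in enumerate(variant.genotypes):
            a, b, phased = gt[0], gt[1], gt[2]
            if a < 0 or b < 0:
                raise FormatError(
                    f"{path}: missing genotype for sample {samples[i]} at {label}"
                )
            if not phased:
                raise FormatError(
                    f"{path}: unphased genotype for sample {samples[i]} at {label}"
                )
            site[0, i], site[1, i] = a, b
        rows.append(site)
    vcf.close()
    if not rows:
        raise FormatError(f"{path}: VCF contains no variant records")
    alleles = np.stack(rows)  # (L, 2, N)
    if major_is == "ref":
        alleles = 1 - alleles
    elif major_is == "frequency":
        flip = alleles.mean(axis=(1, 2)) < 0.5
        alleles[flip] = 1 - alleles[flip]
    return GenotypeTensor(alleles, samples, generation=0)


# ---------------------------------------------------------------------------
# haplotype table TSV
# ---------------------------------------------------------------------------

def write_haplotype_tsv(genotypes: GenotypeTensor, path: str) -> None:
    """Two rows per individual (``hap`` 1 and 2), allele columns a1..aL."""
    L, _, N = genotypes.alleles.shape
    records = []
    for i in range(N):
        for m in (0, 1):
            records.append(
                [genotypes.individual_ids[i], m + 1, *genotypes.alleles[:, m, i]]
            )
    frame = pd.DataFrame(records, columns=["id", "hap", *[f"a{l+1}" for l in range(L)]])
    frame.to_csv(path, sep="\t", index=False)


def read_haplotype_tsv(path: str) -> GenotypeTensor:
    """Inverse of :func:`write_haplotype_tsv` (read∘write = identity)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    expected_prefix = ["id", "hap"]
    if list(frame.columns[:2]) != expected_prefix or len(frame.columns) < 3:
        raise FormatError(f"{path}: header must start with 'id\\thap\\ta1...'")
    allele_cols = list(frame.columns[2:])
    if allele_cols != [f"a{l+1}" for l in range(len(allele_cols))]:
        raise FormatError(f"{path}: allele columns must be named a1..aL in order")
    seen: dict[str, dict[int, np.ndarray]] = {}
    order: list[str] = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        ind = str(row.id)
        try:
            hap = int(row.hap)
        except (TypeError, ValueError):
            raise FormatError(f"{path}: line {row_number}: hap must be 1 or 2")
        if hap not in (1, 2):
            raise FormatError(f"{path}: line {row_number}: hap must be 1 or 2")
        values = np.asarray(row[2:], dtype=object)
        if not np.isin(values, ("0", "1")).all():
            raise FormatError(f"{path}: line {row_number}: alleles must be 0 or 1")
        if ind not in seen:
            seen[ind] = {}
            order.append(ind)
        if hap in seen[ind]:
            raise FormatError(f"{path}: line {row_number}: duplicated (id={ind}, hap={hap})")
        seen[ind][hap] = values.astype(np.uint8)
    for ind in order:
        if set(seen[ind]) != {1, 2}:
            raise FormatError(f"{path}: individual {ind} does not have exactly haps 1 and 2")
    L = len(allele_cols)
    alleles = np.empty((L, 2, len(order)), dtype=np.uint8)
    for i, ind in enumerate(order):
        alleles[:, 0, i] = seen[ind][1]
        alleles[:, 1, i] = seen[ind][2]
    return GenotypeTensor(alleles, order, generation=0)


# ---------------------------------------------------------------------------
# effects and map TSV
# ---------------------------------------------------------------------------

def write_effects_tsv(trait: TraitModel, path: str, markers: list[str] | None = None) -> None:
    markers = markers or [f"m{l+1}" for l in range(trait.n_loci)]
    pd.DataFrame({"marker": markers, "beta": trait.beta}).to_csv(
        path, sep="\t", index=False
    )


def read_effects_tsv(path: str, mu: float = 0.0) -> TraitModel:
    """Columns ``marker<TAB>beta``; marker order must match the genotype file."""
    frame = pd.read_csv(path, sep="\t")
    if list(frame.columns) != ["marker", "beta"]:
        raise FormatError(f"{path}: expected columns 'marker\\tbeta'")
    beta = frame["beta"].to_numpy(dtype=float)
    if not np.isfinite(beta).all():
        bad = frame["marker"][~np.isfinite(beta)].iloc[0]
        raise FormatError(f"{path}: non-finite effect at marker {bad}")
    return TraitModel(beta=beta, mu=mu)


def write_map_tsv(gmap: GeneticMap, path: str, markers: list[str] | None = None) -> None:
    """Writes the ``r_next`` dialect: recombination to the next locus
    (last locus of each chromosome carries 0.5 by convention)."""
    L = gmap.n_loci
    markers = markers or [f"m{l+1}" for l in range(L)]
    r_next = np.append(gmap.recomb, 0.5)
    pd.DataFrame(
        {"marker": markers, "chrom": gmap.chrom, "r_next": r_next}
    ).to_csv(path, sep="\t", index=False)


def read_map_tsv(path: str, markers: list[str] | None = None) -> GeneticMap:
    """Columns ``marker chrom pos_cM`` or ``marker chrom r_next``.

    With ``pos_cM``, interval lengths are converted through Haldane's
    function; chromosome boundaries are forced to ``r = 0.5``.  If
    ``markers`` is given the file's marker order must match it exactly.
    """
    frame = pd.read_csv(path, sep="\t")
    cols = list(frame.columns)
    if cols[:2] != ["marker", "chrom"] or len(cols) != 3 or cols[2] not in ("pos_cM", "r_next"):
        raise FormatError(
            f"{path}: expected columns 'marker\\tchrom\\tpos_cM' or 'marker\\tchrom\\tr_next'"
        )
    if markers is not None:
        file_markers = frame["marker"].astype(str).tolist()
        if file_markers != [str(m) for m in markers]:
            first = next(
                (a for a, b in zip(file_markers, markers) if a != str(b)),
                file_markers[min(len(markers), len(file_markers)) - 1] if file_markers else "?",
            )
            raise FormatError(f"{path}: marker order mismatch near marker {first}")
    chrom_labels = frame["chrom"].tolist()
    codes: dict = {}
    chrom = np.empty(len(chrom_labels), dtype=int)
    for idx, label in enumerate(chrom_labels):
        if label not in codes:
            codes[label] = len(codes)
        chrom[idx] = codes[label]
    if np.any(np.diff(chrom) < 0):
        raise FormatError(f"{path}: chromosomes must be grouped (non-interleaved)")
    L = len(frame)
    if L < 1:
        raise FormatError(f"{path}: empty map")
    if cols[2] == "pos_cM":
        pos = frame["pos_cM"].to_numpy(dtype=float)
        d = np.diff(pos)
        same_chrom = np.diff(chrom) == 0
        if np.any(d[same_chrom] < 0):
            bad = frame["marker"][1:][same_chrom & (d < 0)].iloc[0]
            raise FormatError(f"{path}: decreasing cM position at marker {bad}")
        recomb = haldane_cm_to_r(np.clip(d, 0.0, None))
    else:
        r_next = frame["r_next"].to_numpy(dtype=float)
        if np.any(r_next < 0) or np.any(r_next > 0.5):
            bad = frame["marker"][(r_next < 0) | (r_next > 0.5)].iloc[0]
            raise FormatError(f"{path}: r_next outside [0, 0.5] at marker {bad}")
        recomb = r_next[:-1].copy()
    if L == 1:
        return GeneticMap(recomb=np.empty(0), chrom=chrom)
    recomb[np.diff(chrom) != 0] = 0.5
    return GeneticMap(recomb=recomb, chrom=chrom)


# ---------------------------------------------------------------------------
# plans, config, summaries
# ---------------------------------------------------------------------------

def write_crosses_tsv(plan: MatingPlan, individual_ids: list[str], path: str) -> None:
    rows = [
        {"parent1": individual_ids[i], "parent2": individual_ids[j]}
        for i, j in plan.pairs
    ]
    pd.DataFrame(rows, columns=["parent1", "parent2"]).to_csv(path, sep="\t", index=False)


def load_config(path: str) -> tuple[ProgramConfig, dict]:
    """Parse a YAML run configuration.

    Top-level keys mirror :class:`ProgramConfig` fields (``N``, ``S``,
    ``T``, ``method``, ``W``, ``lambda``, ``gamma``, ``K``,
    ``n_replicates``, ``seed``, ``n_blocks``, ``eval_lambda``); a
    ``data`` mapping (haplotypes/effects/map paths) or a ``synth``
    mapping (generator parameters) supplies the inputs and is returned
    unparsed alongside the config.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: configuration must be a YAML mapping")
    spec = LookAheadSpec(
        W=int(raw.get("W", 3)),
        discount=float(raw.get("lambda", 0.1)),
        gamma=float(raw.get("gamma", 0.8)),
        K=int(raw.get("K", 500)),
    )
    try:
        config = ProgramConfig(
            N=int(raw.get("N", 200)),
            S=int(raw.get("S", 10)),
            T=int(raw.get("T", 10)),
            method=str(raw.get("method", "pvlas")),
            spec=spec,
            n_replicates=int(raw.get("n_replicates", 1)),
            seed=int(raw.get("seed", 0)),
            n_blocks=(int(raw["n_blocks"]) if raw.get("n_blocks") is not None else None),
            eval_discount=(
                float(raw["eval_lambda"]) if raw.get("eval_lambda") is not None else None
            ),
        )
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: invalid configuration: {exc}") from exc
    data_spec = {k: raw[k] for k in ("data", "synth") if k in raw}
    return config, data_spec


def write_summary_json(summary: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
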