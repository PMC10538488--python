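"""Readers and writers for the on-disk formats.

Phased genotypes travel as VCF (canonical interchange, parsed with cyvcf2)
or as a dependency-light haplotype TSV; expression matrices, eQTL maps and
genetic maps are TSVs with documented schemas.  Trained models serialize to
versioned JSON bundles that carry a hash of the panel they were trained
against, so linking can refuse a mismatched panel/model combination.

Coordinates are 1-based and inclusive throughout (VCF convention); alleles
are coded 0 = REF, 1 = ALT, exactly as oriented in the file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .baselines import EBLParams, GNBParams
from .dsm import (
    DSMParams,
    EQTLMap,
    ExpressionProfile,
    GenotypeProfile,
    QTLFactorParams,
)
from .hmm import HaplotypePanel, Haplotype, HMMParams

logger = logging.getLogger("dsmlink")

__all__ = [
    "read_phased_vcf",
    "write_phased_vcf",
    "read_haplotypes_tsv",
    "write_haplotypes_tsv",
    "profiles_to_panel",
    "read_expression",
    "write_expression",
    "read_eqtl_map",
    "write_eqtl_map",
    "read_genetic_map",
    "write_genetic_map",
    "panel_hash",
    "save_dsm",
    "load_dsm",
    "save_gnb",
    "load_gnb",
    "save_ebl",
    "load_ebl",
    "write_provenance",
]

BUNDLE_VERSION = 1
DEFAULT_CM_PER_SITE = 0.01


class UnphasedGenotypeError(ValueError):
    """A VCF record carries an unphased genotype under strict parsing."""


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def read_phased_vcf(
    path: str | Path,
    variant_subset: list[str] | None = None,
    strict: bool = True,
) -> tuple[list[GenotypeProfile], list[str], np.ndarray]:
    """Read phased biallelic genotypes from a VCF.

    Returns (profiles, variant_ids, positions).  Multiallelic records are
    skipped with a warning; unphased records raise under ``strict`` and are
    skipped otherwise.  If ``variant_subset`` is given, only those variant
    IDs are kept and every requested ID must be present.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    wanted = set(variant_subset) if variant_subset is not None else None
    ids: list[str] = []
    positions: list[int] = []
    mat_cols: list[np.ndarray] = []
    pat_cols: list[np.ndarray] = []
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if len(rec.ALT) != 1:
            warnings.warn(f"skipping non-biallelic record {vid}")
            continue
        if wanted is not None and vid not in wanted:
            continue
        gts = rec.genotype.array()
        if np.any(gts[:, 2] == 0):
            if strict:
                raise UnphasedGenotypeError(f"unphased genotype at record {vid}")
            warnings.warn(f"skipping unphased record {vid}")
            continue
        if np.any(gts[:, :2] < 0):
            if strict:
                raise ValueError(f"missing genotype at record {vid}")
            warnings.warn(f"skipping record with missing genotypes {vid}")
            continue
        ids.append(vid)
        positions.append(rec.POS)
        mat_cols.append(gts[:, 0].astype(np.int8))
        pat_cols.append(gts[:, 1].astype(np.int8))
    vcf.close()
    if wanted is not None:
        missing = wanted - set(ids)
        if missing:
            raise ValueError(f"variants missing from VCF: {sorted(missing)[:5]} ...")
    if not ids:
        return [], [], np.empty(0, dtype=np.int64)
    M = np.stack(mat_cols, axis=1)
    P = np.stack(pat_cols, axis=1)
    profiles = [
        GenotypeProfile(Haplotype(M[i]), Haplotype(P[i]), samples[i])
        for i in range(len(samples))
    ]
    return profiles, ids, np.asarray(positions, dtype=np.int64)


def write_phased_vcf(
    path: str | Path,
    profiles: list[GenotypeProfile],
    variant_ids: list[str],
    positions: np.ndarray,
    chrom: str = "1",
) -> None:
    """Write phased genotypes as a minimal VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = [p.sample_id or f"S{i}" for i, p in enumerate(profiles)]
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for s, vid in enumerate(variant_ids):
            gts = "\t".join(
                f"{p.maternal.alleles[s]}|{p.paternal.alleles[s]}" for p in profiles
            )
            fh.write(f"{chrom}\t{positions[s]}\t{vid}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def read_haplotypes_tsv(path: str | Path) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray, list[str]]:
    """Read a haplotype TSV: variant_id, pos, cM, then one column per haplotype.

    Returns (alleles (H, V), variant_ids, positions, genetic_pos, hap_names).
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    hap_cols = [c for c in df.columns if c not in ("variant_id", "pos", "cM")]
    alleles = df[hap_cols].to_numpy(dtype=np.int8).T
    return (
        alleles,
        df["variant_id"].tolist(),
        df["pos"].to_numpy(dtype=np.int64),
        df["cM"].to_numpy(dtype=np.float64),
        hap_cols,
    )


def write_haplotypes_tsv(path: str | Path, panel: HaplotypePanel, hap_names: list[str] | None = None) -> None:
    names = hap_names or [f"hap{k}" for k in range(panel.K)]
    df = pd.DataFrame({"variant_id": panel.variant_ids, "pos": panel.positions, "cM": panel.genetic_pos})
    for k, name in enumerate(names):
        df[name] = panel.alleles[k]
    df.to_csv(path, sep="\t", index=False)


def read_panel_tsv(path: str | Path) -> HaplotypePanel:
    alleles, ids, pos, cm, _ = read_haplotypes_tsv(path)
    return HaplotypePanel(alleles, ids, pos, cm)


def profiles_to_panel(
    profiles: list[GenotypeProfile],
    variant_ids: list[str],
    positions: np.ndarray,
    genetic_pos: np.ndarray | None = None,
) -> HaplotypePanel:
    """Stack phased genotype profiles into a haplotype panel.

    Without a genetic map the panel falls back to a uniform rate of
    ``DEFAULT_CM_PER_SITE`` cM per site (with a warning).
    """
    if genetic_pos is None:
        warnings.warn("no genetic map supplied; assuming uniform recombination rate")
        genetic_pos = np.arange(len(variant_ids), dtype=np.float64) * DEFAULT_CM_PER_SITE
    haps = []
    for p in profiles:
        haps.append(p.maternal.alleles)
        haps.append(p.paternal.alleles)
    return HaplotypePanel(np.stack(haps), variant_ids, positions, genetic_pos)


# ---------------------------------------------------------------------------
# Expression, eQTL map, genetic map
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> list[ExpressionProfile]:
    """Read a genes x samples expression TSV (first column: gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene IDs in expression matrix")
    values = df.to_numpy(dtype=np.float64)
    if not np.isfinite(values).all():
        raise ValueError("non-numeric or non-finite expression cells")
    genes = df.index.astype(str).tolist()
    return [
        ExpressionProfile(values[:, j], genes, sample_id=str(col))
        for j, col in enumerate(df.columns)
    ]


def write_expression(path: str | Path, profiles: list[ExpressionProfile]) -> None:
    genes = profiles[0].gene_ids
    data = {p.sample_id or f"S{i}": p.values for i, p in enumerate(profiles)}
    pd.DataFrame(data, index=pd.Index(genes, name="gene_id")).to_csv(path, sep="\t")


def read_eqtl_map(path: str | Path, variant_ids: list[str]) -> EQTLMap:
    """Read an eQTL map TSV (eqtl_id, variant_id, gene_ids, direction,
    significance) and resolve variant IDs against the genotype data.

    eQTL records whose variant is absent from ``variant_ids`` are dropped
    with a logged count; records sharing a variant are merged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    index = {v: i for i, v in enumerate(variant_ids)}
    present = df["variant_id"].isin(index)
    dropped = int((~present).sum())
    if dropped:
        logger.warning("dropping %d eQTL record(s) absent from the genotype data", dropped)
    df = df[present]
    if df.empty:
        raise ValueError("no eQTL records overlap the genotype data")
    return EQTLMap.from_records(
        [index[v] for v in df["variant_id"]],
        [str(g).split(",") for g in df["gene_ids"]],
        significance=(
            df["significance"].astype(float).to_numpy()
            if "significance" in df
            else None
        ),
        direction=(
            df["direction"].astype(float).to_numpy() if "direction" in df else None
        ),
        eqtl_ids=df["eqtl_id"].tolist() if "eqtl_id" in df else None,
    )


def write_eqtl_map(path: str | Path, eqtl_map: EQTLMap, variant_ids: list[str]) -> None:
    rows = {
        "eqtl_id": eqtl_map.eqtl_ids,
        "variant_id": [variant_ids[s] for s in eqtl_map.site_indices],
        "gene_ids": [",".join(g) for g in eqtl_map.egene_sets],
    }
    if eqtl_map.direction is not None:
        rows["direction"] = eqtl_map.direction
    if eqtl_map.significance is not None:
        rows["significance"] = eqtl_map.significance
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genetic_map(path: str | Path, variant_ids: list[str]) -> np.ndarray:
    """Read a genetic map TSV (variant_id, cM) aligned to the variant order.

    A missing cM column falls back to a uniform rate with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    if "cM" not in df.columns:
        warnings.warn("genetic map lacks a cM column; assuming uniform rate")
        return np.arange(len(variant_ids), dtype=np.float64) * DEFAULT_CM_PER_SITE
    cm = dict(zip(df["variant_id"], df["cM"].astype(float)))
    try:
        return np.array([cm[v] for v in variant_ids], dtype=np.float64)
    except KeyError as exc:
        raise ValueError(f"variant {exc.args[0]!r} missing from genetic map") from exc


def write_genetic_map(path: str | Path, variant_ids: list[str], genetic_pos: np.ndarray) -> None:
    pd.DataFrame({"variant_id": variant_ids, "cM": genetic_pos}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Model bundles and provenance
# ---------------------------------------------------------------------------


def panel_hash(panel: HaplotypePanel) -> str:
    h = hashlib.sha256()
    h.update("\n".join(panel.variant_ids).encode())
    h.update(panel.alleles.tobytes())
    return h.hexdigest()[:16]


def _eqtl_map_json(eqtl_map: EQTLMap, variant_ids: list[str]) -> list[dict]:
    return [
        {
            "eqtl_id": eqtl_map.eqtl_ids[i],
            "variant_id": variant_ids[int(s)],
            "gene_ids": eqtl_map.egene_sets[i],
            "significance": (
                None if eqtl_map.significance is None else float(eqtl_map.significance[i])
            ),
            "direction": (
                None if eqtl_map.direction is None else float(eqtl_map.direction[i])
            ),
        }
        for i, s in enumerate(eqtl_map.site_indices)
    ]


def _eqtl_map_from_json(records: list[dict], variant_ids: list[str]) -> EQTLMap:
    index = {v: i for i, v in enumerate(variant_ids)}
    return EQTLMap(
        [index[r["variant_id"]] for r in records],
        [r["gene_ids"] for r in records],
        significance=np.array([r.get("significance") or 0.0 for r in records]),
        direction=(
            np.array([r["direction"] for r in records])
            if all(r.get("direction") is not None for r in records)
            else None
        ),
        eqtl_ids=[r["eqtl_id"] for r in records],
    )


def save_dsm(path: str | Path, params: DSMParams) -> None:
    """Serialize a trained DSM to a versioned JSON bundle (panel excluded;
    the bundle pins the panel by hash)."""
    bundle = {
        "format": "dsmlink-dsm",
        "version": BUNDLE_VERSION,
        "panel_hash": panel_hash(params.panel),
        "hmm": {
            "switch_prob": params.hmm.switch_prob.tolist(),
            "emission_error": params.hmm.emission_error,
            "prior": params.hmm.prior.tolist(),
        },
        "eqtl_map": _eqtl_map_json(params.eqtl_map, params.panel.variant_ids),
        "factors": [
            {
                "eqtl_id": params.eqtl_map.eqtl_ids[i],
                "gene_ids": params.eqtl_map.egene_sets[i],
                "alpha": float(params.qtl.alphas[i]),
                "betas": params.qtl.betas[i].tolist(),
            }
            for i in range(params.eqtl_map.n_eqtls)
        ],
        "gene_ids": params.gene_ids,
        "gene_means": np.asarray(params.gene_means).tolist(),
        "gene_sds": np.asarray(params.gene_sds).tolist(),
    }
    Path(path).write_text(json.dumps(bundle, indent=1))


def load_dsm(path: str | Path, panel: HaplotypePanel, force: bool = False) -> DSMParams:
    bundle = json.loads(Path(path).read_text())
    if bundle.get("format") != "dsmlink-dsm":
        raise ValueError("not a DSM bundle")
    if bundle["panel_hash"] != panel_hash(panel) and not force:
        raise ValueError(
            "panel hash mismatch: the model was trained against a different "
            "reference panel (use force=True to override)"
        )
    hmm = HMMParams(
        np.array(bundle["hmm"]["switch_prob"]),
        bundle["hmm"]["emission_error"],
        np.array(bundle["hmm"]["prior"]),
    )
    eqtl_map = _eqtl_map_from_json(bundle["eqtl_map"], panel.variant_ids)
    qtl = QTLFactorParams(
        np.array([f["alpha"] for f in bundle["factors"]]),
        [np.array(f["betas"]) for f in bundle["factors"]],
    )
    return DSMParams(
        hmm,
        qtl,
        eqtl_map,
        panel,
        gene_ids=list(bundle["gene_ids"]),
        gene_means=np.array(bundle["gene_means"]),
        gene_sds=np.array(bundle["gene_sds"]),
    )


def save_gnb(path: str | Path, params: GNBParams, variant_ids: list[str]) -> None:
    bundle = {
        "format": "dsmlink-gnb",
        "version": BUNDLE_VERSION,
        "eqtl_map": _eqtl_map_json(params.eqtl_map, variant_ids),
        "gene_ids": params.gene_ids,
        "means": params.means.tolist(),
        "sds": params.sds.tolist(),
        "priors": params.priors.tolist(),
    }
    Path(path).write_text(json.dumps(bundle, indent=1))


def load_gnb(path: str | Path, variant_ids: list[str]) -> GNBParams:
    bundle = json.loads(Path(path).read_text())
    if bundle.get("format") != "dsmlink-gnb":
        raise ValueError("not a GNB bundle")
    return GNBParams(
        _eqtl_map_from_json(bundle["eqtl_map"], variant_ids),
        list(bundle["gene_ids"]),
        np.array(bundle["means"]),
        np.array(bundle["sds"]),
        np.array(bundle["priors"]),
    )


def save_ebl(path: str | Path, params: EBLParams, variant_ids: list[str]) -> None:
    bundle = {
        "format": "dsmlink-ebl",
        "version": BUNDLE_VERSION,
        "gnb": {
            "eqtl_map": _eqtl_map_json(params.gnb.eqtl_map, variant_ids),
            "gene_ids": params.gnb.gene_ids,
            "means": params.gnb.means.tolist(),
            "sds": params.gnb.sds.tolist(),
            "priors": params.gnb.priors.tolist(),
        },
        "extremity_q": params.extremity_q,
        "corr_min": params.corr_min,
        "penalty": params.penalty,
        "direction": params.direction.tolist(),
        "lo_thresh": params.lo_thresh.tolist(),
        "hi_thresh": params.hi_thresh.tolist(),
        "active": params.active.astype(int).tolist(),
    }
    Path(path).write_text(json.dumps(bundle, indent=1))


def load_ebl(path: str | Path, variant_ids: list[str]) -> EBLParams:
    bundle = json.loads(Path(path).read_text())
    if bundle.get("format") != "dsmlink-ebl":
        raise ValueError("not an EBL bundle")
    g = bundle["gnb"]
    gnb = GNBParams(
        _eqtl_map_from_json(g["eqtl_map"], variant_ids),
        list(g["gene_ids"]),
        np.array(g["means"]),
        np.array(g["sds"]),
        np.array(g["priors"]),
    )
    return EBLParams(
        gnb=gnb,
        extremity_q=bundle["extremity_q"],
        corr_min=bundle["corr_min"],
        penalty=bundle["penalty"],
        direction=np.array(bundle["direction"]),
        lo_thresh=np.array(bundle["lo_thresh"]),
        hi_thresh=np.array(bundle["hi_thresh"]),
        active=np.array(bundle["active"], dtype=bool),
    )


def write_provenance(path: str | Path, args: dict, seed: int | None) -> None:
    """Record the exact configuration of a CLI run for reproducibility."""
    from . import __version__

    payload = {
        "dsmlink_version": __version__,
        "seed": seed,
        "config": {k: (str(v) if isinstance(v, Path) else v) for k, v in args.items()},
        "config_hash": hashlib.sha256(
            json.dumps(args, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
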