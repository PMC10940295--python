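"""VCF 4.2 import/export for the payloads the workbench exchanges.

Four payload kinds are supported, mirroring the files a real imputation
pipeline passes around:

* panel   — phased reference haplotypes, FORMAT GT (``0|1``), with a
            sidecar TSV genetic map (chrom, pos, cM);
* gl      — genotype likelihoods for imputation input, FORMAT GT:PL:DP
            (GT is ``./.``; depth-0 sites are written with the flat PL
            0,0,0 and never omitted);
* calls   — hard validation calls, FORMAT GT:DP;
* imputed — imputation output, FORMAT GT:DS:GP (GP rounded to 6 decimals),
            with the model tag and parameter hash in INFO.

Files are written as plain text and parsed back with cyvcf2.  A light
pre-scan gives line-numbered messages for malformed records before the
htslib parser sees them.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotyping import MISSING, GenotypeCalls, GenotypeLikelihoods
from .imputation import ImputedGenotypes
from .popgen_sim import GeneticMap, SitePanel

__all__ = [
    "write_panel_vcf", "read_panel_vcf",
    "write_gl_vcf", "read_gl_vcf",
    "write_calls_vcf", "read_calls_vcf",
    "write_imputed_vcf", "read_imputed_vcf",
    "write_genetic_map", "read_genetic_map",
]

_HEADER_COMMON = "##fileformat=VCFv4.2\n"
_KNOWN_FORMAT = {"GT", "PL", "DP", "GP", "DS"}


def _contig_line(chrom: str, length: int) -> str:
    return f"##contig=<ID={chrom},length={length}>\n"


def _scan_vcf(path) -> None:
    """Cheap structural validation with line-numbered errors."""
    n_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##"):
                continue
            line = line.rstrip("\n")
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                if len(fields) < 10:
                    raise ValueError(f"line {lineno}: header has no sample columns")
                n_cols = len(fields)
                continue
            if n_cols is None:
                raise ValueError(f"line {lineno}: record before #CHROM header")
            if len(fields) != n_cols:
                raise ValueError(
                    f"line {lineno}: expected {n_cols} columns, found {len(fields)}"
                )
            try:
                int(fields[1])
            except ValueError:
                raise ValueError(f"line {lineno}: POS '{fields[1]}' is not an integer")
    if n_cols is None:
        raise ValueError("no #CHROM header line found (truncated file?)")


def _warn_unknown_format(path) -> None:
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                continue
            keys = set(line.split("\t")[8].split(":"))
            unknown = keys - _KNOWN_FORMAT
            if unknown:
                warnings.warn(f"ignoring unknown FORMAT keys: {sorted(unknown)}",
                              stacklevel=3)
            break


def write_genetic_map(gmap: GeneticMap, path, chrom: str = "1") -> None:
    pd.DataFrame({"chrom": chrom, "pos": gmap.positions, "cM": gmap.cm}).to_csv(
        path, sep="\t", index=False
    )


def read_genetic_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    return GeneticMap(positions=df["pos"].to_numpy(np.int64),
                      cm=df["cM"].to_numpy(float))


def write_panel_vcf(panel: SitePanel, path, map_path=None) -> None:
    """Phased panel haplotypes as diploid samples with ``a|b`` genotypes."""
    H = panel.n_hap
    sample_names = [f"{panel.pop_of_hap[2 * i]}_h{2 * i}" for i in range(H // 2)]
    with open(path, "w") as fh:
        fh.write(_HEADER_COMMON)
        fh.write(_contig_line(panel.chrom, panel.genome_length))
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        for m in range(panel.n_sites):
            gts = "\t".join(
                f"{panel.hap[2 * i, m]}|{panel.hap[2 * i + 1, m]}"
                for i in range(H // 2)
            )
            fh.write(
                f"{panel.chrom}\t{panel.positions[m]}\t.\t{panel.ref_base[m]}\t"
                f"{panel.alt_base[m]}\t.\tPASS\t.\tGT\t{gts}\n"
            )
    if map_path is not None:
        write_genetic_map(panel.map, map_path, chrom=panel.chrom)


def read_panel_vcf(path, map_path=None) -> SitePanel:
    _scan_vcf(path)
    _warn_unknown_format(path)
    vcf = VCF(str(path))
    samples = vcf.samples
    pops = [s.rsplit("_h", 1)[0] for s in samples]
    chrom = None
    genome_length = None
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig"):
            body = line[line.index("<") + 1:line.rindex(">")]
            kv = dict(item.split("=", 1) for item in body.split(","))
            chrom = kv.get("ID")
            genome_length = int(kv.get("length", 0))
    positions, ref, alt, rows = [], [], [], []
    for v in vcf:
        positions.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        g = np.array(v.genotypes)[:, :2]
        rows.append(g.reshape(-1))
    hap = np.array(rows, dtype=np.uint8).T  # (H, M)
    positions = np.array(positions, dtype=np.int64)
    gmap = (read_genetic_map(map_path) if map_path is not None
            else GeneticMap.uniform(positions))
    return SitePanel(
        chrom=chrom or "1",
        positions=positions,
        ref_base=np.array(ref, dtype="<U1"),
        alt_base=np.array(alt, dtype="<U1"),
        hap=hap,
        pop_of_hap=np.repeat(pops, 2),
        map=gmap,
        genome_length=genome_length or int(positions[-1]),
    )


def write_gl_vcf(gl: GenotypeLikelihoods, panel: SitePanel, path,
                 sample: str = "target") -> None:
    """Genotype likelihoods as FORMAT GT:PL:DP; flat-triple sites included."""
    pl = np.rint(np.minimum(gl.pl, 255)).astype(int)
    with open(path, "w") as fh:
        fh.write(_HEADER_COMMON)
        fh.write(_contig_line(panel.chrom, panel.genome_length))
        fh.write(f"##paleoimpute_gl_model={gl.model}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred likelihoods">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for m in range(panel.n_sites):
            fh.write(
                f"{panel.chrom}\t{panel.positions[m]}\t.\t{panel.ref_base[m]}\t"
                f"{panel.alt_base[m]}\t.\tPASS\t.\tGT:PL:DP\t"
                f"./.:{pl[m, 0]},{pl[m, 1]},{pl[m, 2]}:{gl.depth[m]}\n"
            )


def read_gl_vcf(path) -> GenotypeLikelihoods:
    _scan_vcf(path)
    _warn_unknown_format(path)
    vcf = VCF(str(path))
    model = "naive"
    for line in vcf.raw_header.splitlines():
        if line.startswith("##paleoimpute_gl_model="):
            model = line.split("=", 1)[1]
    pls, dps = [], []
    for v in vcf:
        pls.append(v.format("PL")[0])
        dps.append(v.format("DP")[0][0])
    return GenotypeLikelihoods.from_pl(
        np.array(pls, dtype=float), np.array(dps, dtype=np.int64), model=model
    )


def write_calls_vcf(calls: GenotypeCalls, panel: SitePanel, path,
                    sample: str = "validation") -> None:
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    depth = calls.depth if calls.depth is not None else np.zeros(calls.n_sites, int)
    with open(path, "w") as fh:
        fh.write(_HEADER_COMMON)
        fh.write(_contig_line(panel.chrom, panel.genome_length))
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for m in range(calls.n_sites):
            fh.write(
                f"{panel.chrom}\t{panel.positions[m]}\t.\t{panel.ref_base[m]}\t"
                f"{panel.alt_base[m]}\t.\tPASS\t.\tGT:DP\t"
                f"{gt_str[int(calls.gt[m])]}:{int(depth[m])}\n"
            )


def read_calls_vcf(path) -> GenotypeCalls:
    _scan_vcf(path)
    _warn_unknown_format(path)
    vcf = VCF(str(path))
    gts, dps = [], []
    for v in vcf:
        a = v.genotypes[0][:2]
        gts.append(MISSING if a[0] < 0 else a[0] + a[1])
        dps.append(v.format("DP")[0][0])
    return GenotypeCalls.from_gt(np.array(gts, dtype=np.int8),
                                 depth=np.array(dps, dtype=np.int64))


def write_imputed_vcf(imp: ImputedGenotypes, panel: SitePanel, path,
                      sample: str = "imputed", params_hash: str = "") -> None:
    """Imputation output as FORMAT GT:DS:GP (GP rounded to 6 decimals)."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write(_HEADER_COMMON)
        fh.write(_contig_line(panel.chrom, panel.genome_length))
        fh.write(f"##paleoimpute_model={imp.model}\n")
        if params_hash:
            fh.write(f"##paleoimpute_params_hash={params_hash}\n")
        fh.write('##INFO=<ID=MODEL,Number=1,Type=String,Description="Imputation model">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Best-guess genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write('##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype posterior">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        best = imp.best_guess
        ds = imp.dosage
        for m in range(imp.n_sites):
            gp = ",".join(f"{x:.6f}" for x in imp.gp[m])
            fh.write(
                f"{panel.chrom}\t{panel.positions[m]}\t.\t{panel.ref_base[m]}\t"
                f"{panel.alt_base[m]}\t.\tPASS\tMODEL={imp.model}\tGT:DS:GP\t"
                f"{gt_str[int(best[m])]}:{ds[m]:.6f}:{gp}\n"
            )


def read_imputed_vcf(path) -> ImputedGenotypes:
    _scan_vcf(path)
    _warn_unknown_format(path)
    vcf = VCF(str(path))
    model = "LS-diploid"
    for line in vcf.raw_header.splitlines():
        if line.startswith("##paleoimpute_model="):
            model = line.split("=", 1)[1]
    gps = []
    for v in vcf:
        gps.append(v.format("GP")[0])
    gp = np.array(gps, dtype=np.float64)
    gp = gp / gp.sum(axis=1, keepdims=True)  # undo 6-decimal rounding drift
    return ImputedGenotypes(gp=gp, model=model)
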