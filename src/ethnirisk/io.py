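"""Readers and writers for the package's file formats.

Formats (all plain text):

* PGS model TSV — ``#name=`` / ``#chek2_safe=`` / one ``#ancestry_params=``
  header line per ancestry (``ancestry,mu,sd,alpha``), then columns
  ``snp_id chr pos effect_allele other_allele weight freq_EUR freq_AFR
  freq_EAS freq_SAS``.  Positions 1-based.
* Genotypes — VCF (DS field preferred, GT fallback; dosages are counted on
  the model's effect allele, flipping 2 - x when the effect allele is REF)
  or a two-column ``snp_id  dosage`` TSV.
* Incidence TSV — ``cancer cohort ethnicity age rate_per_100k``; rates are
  stored internally as events per person-year.
* IRR / composition / model configuration — YAML.

Readers reject malformed rows with line-numbered errors; every writer/reader
pair round-trips.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from pathlib import Path

import numpy as np
import yaml

from .incidence import IncidenceTable, IrrSet, EthnicComposition
from .pgs import ANCESTRIES, AncestryParams, AncestryProfile, PgsModel, SnpEntry
from .risk import FactorSystem, MajorGene, ModelConfig, PolygeneSpec
from .subtypes import SUBTYPES, SubtypeDistribution, SubtypeEffect
from .synthetic import make_toy_incidence  # noqa: F401  (re-exported for CLI fixtures)

logger = logging.getLogger("ethnirisk")

_FREQ_COLS = {"European": "freq_EUR", "African": "freq_AFR",
              "EastAsian": "freq_EAS", "SouthAsian": "freq_SAS"}
_AMBIGUOUS = ({"A", "T"}, {"C", "G"})

__all__ = [
    "read_pgs_model", "write_pgs_model",
    "read_dosage_tsv", "write_dosage_tsv",
    "read_vcf_dosages", "write_vcf",
    "read_incidence", "write_incidence",
    "read_irr", "write_irr", "read_composition",
    "read_subtype_distribution", "read_subtype_effects",
    "read_config", "write_report",
    "parse_ancestry_spec",
]


# ---------------------------------------------------------------------------
# PGS model files


def write_pgs_model(model: PgsModel, path) -> None:
    lines = [f"#name={model.name}", f"#chek2_safe={int(model.chek2_safe)}"]
    for anc in ANCESTRIES:
        if anc in model.params_by_ancestry:
            p = model.params_by_ancestry[anc]
            lines.append(f"#ancestry_params={anc},{p.mu!r},{p.sd!r},{p.alpha!r}")
    header = ["snp_id", "chr", "pos", "effect_allele", "other_allele", "weight"]
    header += [_FREQ_COLS[a] for a in ANCESTRIES]
    lines.append("\t".join(header))
    for snp in model.snps:
        chrom, pos, ref, alt = snp.snp_id.split("_")
        other = ref if snp.effect_allele == alt else alt
        row = [snp.snp_id, chrom, pos, snp.effect_allele, other, repr(snp.weight)]
        row += [repr(snp.freq_by_ancestry[a]) for a in ANCESTRIES]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_pgs_model(path) -> PgsModel:
    name, chek2_safe, params = None, False, {}
    snps: list[SnpEntry] = []
    expected_cols = 6 + len(ANCESTRIES)
    saw_header = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#name="):
            name = line.split("=", 1)[1]
            continue
        if line.startswith("#chek2_safe="):
            chek2_safe = bool(int(line.split("=", 1)[1]))
            continue
        if line.startswith("#ancestry_params="):
            try:
                anc, mu, sd, alpha = line.split("=", 1)[1].split(",")
                params[anc] = AncestryParams(float(mu), float(sd), float(alpha))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad ancestry_params line: {exc}")
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "snp_id":
            saw_header = True
            continue
        if len(fields) != expected_cols:
            raise ValueError(
                f"{path}:{lineno}: expected {expected_cols} columns, got {len(fields)}"
            )
        try:
            snps.append(SnpEntry(
                snp_id=fields[0],
                effect_allele=fields[3],
                weight=float(fields[5]),
                freq_by_ancestry={a: float(fields[6 + i]) for i, a in enumerate(ANCESTRIES)},
            ))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}")
    if name is None or not saw_header or not snps:
        raise ValueError(f"{path}: truncated or malformed PGS model file")
    return PgsModel(name=name, snps=snps, params_by_ancestry=params, chek2_safe=chek2_safe)


# ---------------------------------------------------------------------------
# Genotypes


def write_dosage_tsv(dosages: dict[str, float], path) -> None:
    lines = ["snp_id\tdosage"]
    lines += [f"{snp}\t{d!r}" for snp, d in dosages.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_dosage_tsv(path) -> dict[str, float]:
    out: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("snp_id"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        try:
            d = float(fields[1])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric dosage {fields[1]!r}")
        if not 0.0 <= d <= 2.0:
            raise ValueError(f"{path}:{lineno}: dosage {d} outside [0, 2]")
        out[fields[0]] = d
    if not out:
        raise ValueError(f"{path}: no dosage rows found")
    return out


def write_vcf(dosages: dict[str, float], path, sample: str = "SAMPLE") -> None:
    """Minimal single-sample VCF with DS (and rounded GT) fields, one record
    per ``chr_pos_ref_alt`` id."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">',
    ]
    chroms = []
    for snp_id in dosages:
        chrom = snp_id.split("_")[0]
        if chrom not in chroms:
            chroms.append(chrom)
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample)
    records = []
    for snp_id, d in dosages.items():
        chrom, pos, ref, alt = snp_id.split("_")
        n_alt = int(round(d))
        gt = ["0/0", "0/1", "1/1"][n_alt]
        records.append((chrom, int(pos),
                        f"{chrom}\t{pos}\t{snp_id}\t{ref}\t{alt}\t.\t.\t.\tGT:DS\t{gt}:{d:g}"))
    records.sort(key=lambda r: (r[0], r[1]))
    lines += [r[2] for r in records]
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf_dosages(path, model: PgsModel, sample: str | None = None) -> dict[str, float]:
    """Effect-allele dosages for the model panel from a VCF.

    DS is preferred over GT.  When the model's effect allele is the record
    REF, the ALT dosage is flipped (2 - x); strand-ambiguous (A/T, C/G)
    sites are accepted as-is with a warning.  Records not in the panel are
    skipped.
    """
    import pysam

    lookup: dict[tuple[str, int], SnpEntry] = {}
    for snp in model.snps:
        chrom, pos, _ref, _alt = snp.snp_id.split("_")
        lookup[(chrom, int(pos))] = snp
    out: dict[str, float] = {}
    n_ambiguous = 0
    with pysam.VariantFile(str(path)) as vcf:
        sample = sample or list(vcf.header.samples)[0]
        for rec in vcf:
            snp = lookup.get((str(rec.chrom), rec.pos))
            if snp is None:
                continue
            alt = rec.alts[0] if rec.alts else None
            if {rec.ref, alt} in _AMBIGUOUS:
                n_ambiguous += 1
            call = rec.samples[sample]
            if "DS" in call and call["DS"] is not None:
                alt_dose = float(call["DS"])
            elif call.get("GT") is not None and None not in call["GT"]:
                alt_dose = float(sum(call["GT"]))
            else:
                continue
            if snp.effect_allele == alt:
                dose = alt_dose
            elif snp.effect_allele == rec.ref:
                dose = 2.0 - alt_dose
            else:
                warnings.warn(
                    f"{snp.snp_id}: effect allele matches neither REF nor ALT; skipped",
                    stacklevel=2,
                )
                continue
            out[snp.snp_id] = dose
    if n_ambiguous:
        warnings.warn(
            f"{n_ambiguous} strand-ambiguous (A/T or C/G) site(s) accepted as-is",
            stacklevel=2,
        )
    if not out:
        raise ValueError(f"{path}: no VCF record matched the model panel")
    return out


# ---------------------------------------------------------------------------
# Incidence tables


def write_incidence(tables, path) -> None:
    """Write one or more incidence tables (rates emitted per 100,000
    person-years, ordered by ethnicity then age)."""
    if isinstance(tables, IncidenceTable):
        tables = [tables]
    lines = ["cancer\tcohort\tethnicity\tage\trate_per_100k"]
    for tab in sorted(tables, key=lambda t: t.ethnicity):
        for age, rate in zip(tab.ages, tab.rates):
            lines.append(f"{tab.cancer}\t{tab.cohort}\t{tab.ethnicity}\t{age}\t"
                         f"{float(rate) * 1e5:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_incidence(path) -> list[IncidenceTable]:
    groups: dict[tuple[str, str, str], list[tuple[int, float]]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("cancer"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
        try:
            age, rate = int(fields[3]), float(fields[4])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}")
        groups.setdefault((fields[0], fields[1], fields[2]), []).append((age, rate / 1e5))
    if not groups:
        raise ValueError(f"{path}: no incidence rows found")
    tables = []
    for (cancer, cohort, ethnicity), rows in groups.items():
        rows.sort()
        ages = np.array([a for a, _ in rows])
        tables.append(IncidenceTable(
            cancer=cancer, cohort=cohort, ethnicity=ethnicity,
            ages=ages, rates=np.array([r for _, r in rows]),
        ))
    return tables


# ---------------------------------------------------------------------------
# YAML blocks


def read_irr(path) -> IrrSet:
    data = yaml.safe_load(Path(path).read_text())
    return IrrSet(reference=data["reference"], values={k: float(v) for k, v in data["values"].items()})


def write_irr(irr: IrrSet, path) -> None:
    Path(path).write_text(yaml.safe_dump(
        {"reference": irr.reference, "values": {k: float(v) for k, v in irr.values.items()}}
    ))


def read_composition(path) -> EthnicComposition:
    data = yaml.safe_load(Path(path).read_text())
    block = data.get("proportions", data)
    return EthnicComposition(proportions={k: float(v) for k, v in block.items()})


def read_subtype_distribution(path) -> SubtypeDistribution:
    """TSV columns: ethnicity  age_band(lo-hi)  p_ER_pos  p_TN  p_ERneg_notTN."""
    table: dict[tuple[tuple[int, int], str], dict[str, float]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("ethnicity"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
        try:
            lo, hi = (int(x) for x in fields[1].split("-"))
            probs = dict(zip(SUBTYPES, (float(v) for v in fields[2:])))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}")
        table[((lo, hi), fields[0])] = probs
    if not table:
        raise ValueError(f"{path}: no subtype rows found")
    return SubtypeDistribution(by_age_ethnicity=table)


def read_subtype_effects(path) -> dict[str, SubtypeEffect]:
    data = yaml.safe_load(Path(path).read_text())
    return {
        gene: SubtypeEffect(
            gene=gene,
            log_or_by_subtype={k: float(v) for k, v in spec["log_or"].items()},
            age_interaction_by_subtype={k: float(v) for k, v in spec.get("age_interaction", {}).items()},
            reference_age=int(spec.get("reference_age", 50)),
        )
        for gene, spec in data.items()
    }


# ---------------------------------------------------------------------------
# Model configuration


def _factor_from_yaml(block) -> FactorSystem:
    levels = tuple(block["levels"])
    return FactorSystem(
        name=block["name"],
        levels=levels,
        log_rr={lv: math.log(float(block["rr"][lv])) for lv in levels},
        prevalence_by_ethnicity={
            eth: {lv: float(p) for lv, p in dist.items()}
            for eth, dist in block["prevalence"].items()
        },
    )


def read_config(path) -> ModelConfig:
    """Model configuration YAML: national incidence (path, relative to the
    config file), optional IRR block, genes, polygene, factor systems and
    PGS parameters."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    tables = read_incidence(path.parent / data["incidence"])
    national = next((t for t in tables if t.ethnicity in ("National", "Unknown")), tables[0])
    irr = None
    if data.get("irr"):
        irr = IrrSet(reference=data["irr"]["reference"],
                     values={k: float(v) for k, v in data["irr"]["values"].items()})
    genes = []
    for g in data.get("genes", []):
        rr = g["rr"]
        if isinstance(rr, dict):  # {age_from: rr} steps
            ages = national.ages
            curve = np.empty(ages.size)
            for age_from, val in sorted((int(a), float(v)) for a, v in rr.items()):
                curve[ages >= age_from] = val
            rr = curve
        genes.append(MajorGene(
            gene=g["gene"],
            pv_frequency_by_ancestry={k: float(v) for k, v in g["frequency"].items()},
            rr_by_age=rr,
        ))
    poly = data.get("polygene", {})
    return ModelConfig(
        cancer=data["cancer"],
        national=national,
        irr=irr,
        genes=genes,
        polygene=PolygeneSpec(sd_by_age=float(poly.get("sd", 1.2)),
                              n_nodes=int(poly.get("nodes", 64))),
        qrf_factors=[_factor_from_yaml(b) for b in data.get("factors", [])],
        birads=_factor_from_yaml(data["birads"]) if data.get("birads") else None,
        pgs_params={anc: AncestryParams(*[float(x) for x in triple])
                    for anc, triple in data.get("pgs_params", {}).items()},
    )


def write_report(results: dict, path) -> None:
    """JSON report writer (deterministic key order)."""
    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple, np.ndarray)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj
    Path(path).write_text(json.dumps(_clean(results), indent=2, sort_keys=True) + "\n")


def parse_ancestry_spec(spec: str) -> AncestryProfile:
    """Parse ``EUR=0.6,AFR=0.4`` style ancestry proportion strings."""
    abbrev = {"EUR": "European", "AFR": "African", "EAS": "EastAsian", "SAS": "SouthAsian"}
    props: dict[str, float] = {}
    for part in spec.split(","):
        key, _, val = part.partition("=")
        key = key.strip()
        anc = abbrev.get(key.upper(), key)
        props[anc] = float(val)
    return AncestryProfile(proportions=props)
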