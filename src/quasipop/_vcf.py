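"""Minimal VCF 4.2 writing/reading for variant calls."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from .pileup_caller import VariantCall

_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=AF,Number=1,Type=Float,Description="Mean alternative allele frequency across configurations">',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##INFO=<ID=AC,Number=1,Type=Integer,Description="Alternative allele count">',
    '##INFO=<ID=NCONF,Number=1,Type=Integer,Description="Number of configurations detecting the site">',
    '##FILTER=<ID=sd2_fail,Description="Frequency vector outside mean +/- 2 SD consensus band">',
    '##FILTER=<ID=low_cov,Description="Depth below minimum coverage">',
    '##FILTER=<ID=low_freq,Description="Frequency at or below threshold">',
]


def write_vcf(
    calls: Sequence[VariantCall],
    reference_id: str,
    reference_length: int,
    path: str | Path,
    meta: dict[str, str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for line in _HEADER_LINES:
            fh.write(line + "\n")
        fh.write(f"##contig=<ID={reference_id},length={reference_length}>\n")
        for key, val in (meta or {}).items():
            fh.write(f"##{key}={val}\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: c.key):
            filt = "PASS" if c.passed else ";".join(sorted(c.filters))
            nconf = sum(1 for e in c.frequency_estimates if e > 0) or 1
            info = f"AF={c.alt_frequency:.6g};DP={c.depth};AC={c.alt_count};NCONF={nconf}"
            fh.write(
                f"{reference_id}\t{c.position}\t.\t{c.ref_allele}\t{c.alt_allele}\t.\t{filt}\t{info}\n"
            )


def read_vcf(path: str | Path) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _, ref, alt, _, filt, info = line.rstrip("\n").split("\t")[:8]
            fields = dict(kv.split("=", 1) for kv in info.split(";") if "=" in kv)
            calls.append(
                VariantCall(
                    position=int(pos),
                    ref_allele=ref,
                    alt_allele=alt,
                    alt_frequency=float(fields.get("AF", "nan")),
                    alt_count=int(fields.get("AC", 0)),
                    depth=int(fields.get("DP", 0)),
                    filters={"PASS"} if filt in ("PASS", ".") else set(filt.split(";")),
                )
            )
    return calls
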