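"""Standard-format readers/writers.

Internal coordinates are 1-based inclusive throughout the package;
conversion to BED / bedGraph 0-based half-open intervals happens here and
only here.  Every writer embeds the seed and a config digest so equal
runs produce byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .types import LeaderAnnotation


def config_digest(obj) -> str:
    """Stable digest of a (nested) configuration mapping."""
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_fasta(leader: LeaderAnnotation, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{leader.name} cds_start={leader.cds_start}\n")
        seq = leader.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    return path


def element_bed_records(leader: LeaderAnnotation):
    """Element track as (chrom, start0, end0, name, score, strand) rows."""
    rows = []
    name = leader.name

    def add(lo: int, hi: int, label: str, score=0):
        rows.append((name, lo - 1, hi, label, score, "+"))

    for st in leader.st_st:
        add(st.start, st.end, "St-st")
    for i, u in enumerate(sorted(leader.uorfs, key=lambda x: x.start), 1):
        end = len(leader.sequence) if u.stopless else u.end
        add(u.start, end, f"uORF{i}_{u.n_codons}codons_frame{u.frame_vs_cds:+d}")
    for s in leader.start_sites:
        add(s.position, s.position + 2, f"{s.codon}_{s.context.label}")
    for h in leader.stem_loops:
        add(h.five_prime_base, h.three_prime_end, f"hairpin_dG{h.delta_G:.2f}")
    for m in leader.methyl_sites:
        cls = "RRACH" if "RRACH" in m.motif_class else "DRACH"
        add(m.position, m.position, f"m6A_{cls}")
    for f in leader.frameshift_signals:
        add(f.interval[0], f.interval[1], f.kind)
    rows.sort(key=lambda r: (r[1], r[3]))
    return rows


def write_bed(leader: LeaderAnnotation, path, header: dict | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {json.dumps(header, sort_keys=True)}\n")
        for row in element_bed_records(leader):
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path


def write_bedgraph(track, path, name: str = "track", header: dict | None = None) -> Path:
    """Write a per-nucleotide array (1-based values) as bedGraph.

    Runs of equal values are merged; zero runs are skipped (a zero track
    yields a valid, interval-free file)."""
    track = np.asarray(track, dtype=float)
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {json.dumps(header, sort_keys=True)}\n")
        fh.write(f'track type=bedGraph name="{name}"\n')
        i = 0
        n = len(track)
        while i < n:
            j = i
            while j < n and track[j] == track[i]:
                j += 1
            if track[i] != 0.0:
                fh.write(f"{name}\t{i}\t{j}\t{track[i]:g}\n")
            i = j
    return path


def read_bedgraph(path, length: int | None = None) -> np.ndarray:
    rows = []
    maxend = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track")):
                continue
            _, s, e, v = line.rstrip("\n").split("\t")
            rows.append((int(s), int(e), float(v)))
            maxend = max(maxend, int(e))
    arr = np.zeros(length if length is not None else maxend)
    for s, e, v in rows:
        arr[s:e] = v
    return arr


def write_json(obj, path, seed: int | None = None, config: dict | None = None) -> Path:
    path = Path(path)
    payload = {"seed": seed, "config_digest": config_digest(config or {}), "data": obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=_coerce)
        fh.write("\n")
    return path


def _coerce(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)
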