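"""Synthetic protein fixtures with planted cleavage motifs and sites.

The generator builds random protein sequences, writes chosen cleavage
motifs into them at recorded positions, and marks phosphorylation sites
on existing S/T/Y residues.  Everything is driven by one integer seed
and a manifest of the planted ground truth is returned, so engine
behaviour can be checked against known answers: every planted motif
start must be recovered by the matching cleavage rule, and every
planted site must appear in the sites table.

These sequences are i.i.d. draws over the 20-letter alphabet; they do
not mimic real amino-acid composition, domain structure, or the
clustering of phosphosites in disordered regions.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_PHOSPHORYLATABLE = "STY"


@dataclass
class FixtureBundle:
    """Generated FASTA text, sites-table text, and ground-truth manifest."""

    fasta_text: str
    sites_text: str
    manifest: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> tuple[Path, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fasta_path = out_dir / "proteins.fasta"
        sites_path = out_dir / "sites.tsv"
        fasta_path.write_text(self.fasta_text)
        sites_path.write_text(self.sites_text)
        return fasta_path, sites_path


def _split_evenly(total: int, bins: int) -> list[int]:
    base, extra = divmod(total, bins)
    return [base + (1 if i < extra else 0) for i in range(bins)]


def generate_fixture(
    seed: int,
    n_proteins: int = 1,
    length: int = 200,
    n_sites: int = 2,
    motifs: dict[str, str] | None = None,
    motifs_per_protein: int = 3,
) -> FixtureBundle:
    """Generate a deterministic fixture panel.

    ``n_sites`` is the total across all proteins, distributed as evenly
    as possible.  ``motifs`` maps an enzyme name to a literal motif
    string planted ``motifs_per_protein`` times per protein at
    non-overlapping positions recorded in the manifest.  Raises when a
    protein ends up with more requested sites than S/T/Y residues.
    """
    if n_proteins < 1 or length < 10 or n_sites < 0:
        raise ValueError("sizes must be positive (length >= 10)")
    motifs = motifs or {}
    for name, motif in motifs.items():
        if not set(motif) <= set(AA_ALPHABET):
            raise ValueError(f"motif for {name!r} has non-residue letters")
        if len(motif) * motifs_per_protein * len(motifs) > length // 2:
            raise ValueError("motifs would occupy most of the sequence")
    rng = random.Random(seed)
    per_protein_sites = _split_evenly(n_sites, n_proteins)

    fasta_lines: list[str] = []
    sites_lines = ["protein_id\tposition\tresidue\tmodification"]
    manifest: dict = {"seed": seed, "proteins": []}

    for idx in range(n_proteins):
        pid = f"SYN{idx + 1:03d}"
        seq = [rng.choice(AA_ALPHABET) for _ in range(length)]

        # Plant motifs at non-overlapping 0-based offsets.
        occupied: set[int] = set()
        planted: list[dict] = []
        for enzyme_name in sorted(motifs):
            motif = motifs[enzyme_name]
            for _ in range(motifs_per_protein):
                for _attempt in range(200):
                    p0 = rng.randrange(0, length - len(motif) + 1)
                    span = set(range(p0, p0 + len(motif)))
                    if not span & occupied:
                        occupied |= span
                        seq[p0 : p0 + len(motif)] = list(motif)
                        planted.append(
                            {
                                "enzyme": enzyme_name,
                                "motif": motif,
                                "position": p0 + 1,
                            }
                        )
                        break
                else:
                    raise ValueError(
                        f"could not place motif {motif!r} in {pid}"
                    )

        sequence = "".join(seq)
        sty = [
            i + 1
            for i, r in enumerate(sequence)
            if r in _PHOSPHORYLATABLE and i not in occupied
        ]
        want = per_protein_sites[idx]
        if want > len(sty):
            raise ValueError(
                f"{pid}: requested {want} sites but only {len(sty)} "
                f"unoccupied S/T/Y residues are available"
            )
        site_positions = sorted(rng.sample(sty, want))
        for pos in site_positions:
            sites_lines.append(
                f"{pid}\t{pos}\t{sequence[pos - 1]}\tphospho"
            )

        fasta_lines.append(f">{pid} synthetic fixture protein {idx + 1}")
        fasta_lines.extend(
            sequence[i : i + 60] for i in range(0, length, 60)
        )
        manifest["proteins"].append(
            {
                "id": pid,
                "length": length,
                "motifs": planted,
                "sites": [
                    {"position": pos, "residue": sequence[pos - 1]}
                    for pos in site_positions
                ],
            }
        )

    return FixtureBundle(
        fasta_text="\n".join(fasta_lines) + "\n",
        sites_text="\n".join(sites_lines) + "\n",
        manifest=manifest,
    )
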