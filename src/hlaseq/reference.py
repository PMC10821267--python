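"""HLA allele reference library.

The typing reference is built from per-exon allele sequences.  Many alleles in
public HLA databases are only partially characterized: frequently just the
exons encoding the peptide-binding site (exons 2 and 3 for Class I, exon 2 for
Class II) are available, since they carry most of the polymorphism.  Missing
exons are reconstructed by copying the sequence from the closest same-locus
allele that does contain them, where "closest" means highest sequence identity
over the exons the two alleles share; ties are resolved in favor of confirmed
and common, well-documented alleles, then by allele name.

G groups — sets of alleles with identical nucleotide sequence across the
peptide-binding exons — are the ambiguity classes at which genotyping accuracy
is conventionally scored.  A multi-allele group is named by the first three
fields of its lowest-numbered member followed by ``G``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import edlib
from Bio import SeqIO

from .errors import DataError, ParseError
from .nomenclature import AlleleName, parse_allele_name, truncate_resolution

STATUS_CWD = "confirmed_common_well_documented"
STATUS_OTHER = "other"

_VALID_BASES = frozenset("ACGT")


def locus_class(locus: str) -> str:
    """Return ``"I"`` or ``"II"`` for an HLA locus name.

    Class II gene names all start with ``D`` (DP/DQ/DR and the non-classical
    DM/DO); everything else (A/B/C, E/F/G) is Class I.
    """
    short = locus.upper().removeprefix("HLA-")
    return "II" if short.startswith("D") else "I"


def peptide_binding_exons(locus: str) -> frozenset[int]:
    """Exons encoding the peptide-binding site: {2, 3} for Class I, {2} for Class II."""
    return frozenset({2, 3}) if locus_class(locus) == "I" else frozenset({2})


@dataclass
class AlleleRecord:
    """One HLA allele: name, per-exon sequences and documentation status.

    ``exons`` maps exon index (1-based) to its nucleotide sequence; absent
    indices mark missing exons.  ``reconstructed_exons`` lists exon indices
    that were filled in from a donor allele (empty on load).
    """

    name: AlleleName
    exons: dict[int, str]
    status: str = STATUS_OTHER
    reconstructed_exons: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.status not in (STATUS_CWD, STATUS_OTHER):
            raise DataError(f"unknown status {self.status!r} for {self.name}")
        for idx, seq in self.exons.items():
            if not seq or set(seq) - _VALID_BASES:
                raise DataError(
                    f"allele {self.name} exon {idx}: sequence must be "
                    f"non-empty uppercase ACGT"
                )
        missing_pb = peptide_binding_exons(self.name.locus) - set(self.exons)
        if missing_pb:
            raise DataError(
                f"allele {self.name} lacks peptide-binding exon(s) "
                f"{sorted(missing_pb)}"
            )
        if not self.reconstructed_exons <= set(self.exons):
            raise DataError(
                f"allele {self.name}: reconstructed_exons not a subset of "
                f"present exons"
            )

    @property
    def original_exons(self) -> set[int]:
        """Exon indices present in the source database (not reconstructed)."""
        return set(self.exons) - self.reconstructed_exons

    def pb_sequence(self) -> str:
        """Concatenated peptide-binding exon sequence (G-group identity key)."""
        return "".join(
            self.exons[i] for i in sorted(peptide_binding_exons(self.name.locus))
        )


@dataclass
class AlleleLibrary:
    """Collection of :class:`AlleleRecord` with a per-locus exon template.

    The exon template records, per locus, the full set of exon indices a
    complete allele is expected to carry (the union over loaded records).
    """

    records: dict[str, AlleleRecord]
    exon_template: dict[str, tuple[int, ...]]
    version: str = "toy"

    @property
    def loci(self) -> set[str]:
        return set(self.exon_template)

    def __len__(self) -> int:
        return len(self.records)

    def by_locus(self, locus: str) -> list[AlleleRecord]:
        return [r for r in self.records.values() if r.name.locus == locus]

    def record(self, name: str | AlleleName) -> AlleleRecord:
        key = str(name)
        if key not in self.records:
            raise DataError(f"allele {key} not in library")
        return self.records[key]

    def transcript(self, name: str | AlleleName) -> str:
        """Concatenated-exon (intron-free) transcript sequence of an allele."""
        rec = self.record(name)
        return concat_exons(rec, self.exon_template[rec.name.locus])

    def is_complete(self) -> bool:
        return all(
            set(rec.exons) >= set(self.exon_template[rec.name.locus])
            for rec in self.records.values()
        )

    # -- persistence ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write the library as FASTA (``>NAME|exon=K``) + TSV sidecar + manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "alleles.fasta", "w") as fa:
            for key in sorted(self.records):
                rec = self.records[key]
                for idx in sorted(rec.exons):
                    fa.write(f">{key}|exon={idx}\n{rec.exons[idx]}\n")
        with open(directory / "alleles.tsv", "w") as tsv:
            tsv.write("name\tlocus\tstatus\texons\treconstructed\n")
            for key in sorted(self.records):
                rec = self.records[key]
                tsv.write(
                    f"{key}\t{rec.name.locus}\t{rec.status}\t"
                    f"{','.join(map(str, sorted(rec.exons)))}\t"
                    f"{','.join(map(str, sorted(rec.reconstructed_exons)))}\n"
                )
        manifest = {
            "library_version": self.version,
            "n_alleles": len(self.records),
            "loci": sorted(self.loci),
            "exon_template": {k: list(v) for k, v in sorted(self.exon_template.items())},
        }
        with open(directory / "manifest.json", "w") as mf:
            json.dump(manifest, mf, indent=2, sort_keys=True)
            mf.write("\n")

    @classmethod
    def load(cls, directory: str | Path) -> "AlleleLibrary":
        directory = Path(directory)
        lib = load_library(directory / "alleles.fasta", directory / "alleles.tsv")
        manifest_path = directory / "manifest.json"
        if manifest_path.exists():
            with open(manifest_path) as mf:
                lib.version = json.load(mf).get("library_version", lib.version)
        return lib


def _read_fasta(path: str | Path):
    """Yield (full header, sequence) from a FASTA file."""
    for record in SeqIO.parse(str(path), "fasta"):
        yield record.description, str(record.seq)


def load_library(fasta_path: str | Path, metadata_path: str | Path) -> AlleleLibrary:
    """Load an allele library from exon FASTA + metadata TSV.

    FASTA headers are ``NAME|exon=K``; the TSV carries at least columns
    ``name`` and ``status``.  Missing exons are simply absent from the FASTA.
    """
    status_map: dict[str, str] = {}
    recon_map: dict[str, set[int]] = {}
    with open(metadata_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            name_col, status_col = header.index("name"), header.index("status")
        except ValueError as exc:
            raise ParseError(f"metadata {metadata_path}: need 'name' and 'status' columns") from exc
        recon_col = header.index("reconstructed") if "reconstructed" in header else None
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            status_map[parts[name_col]] = parts[status_col]
            if recon_col is not None and recon_col < len(parts) and parts[recon_col]:
                recon_map[parts[name_col]] = {int(x) for x in parts[recon_col].split(",")}

    exons_by_allele: dict[str, dict[int, str]] = {}
    for header, seq in _read_fasta(fasta_path):
        name_part, _, exon_part = header.partition("|")
        if not exon_part.startswith("exon="):
            raise ParseError(f"FASTA header {header!r}: expected 'NAME|exon=K'")
        exon_idx = int(exon_part.removeprefix("exon="))
        canonical = str(parse_allele_name(name_part))
        bad = set(seq.upper()) - _VALID_BASES
        if bad:
            raise DataError(
                f"allele {canonical} exon {exon_idx}: non-ACGT characters {sorted(bad)}"
            )
        exdict = exons_by_allele.setdefault(canonical, {})
        if exon_idx in exdict:
            raise DataError(f"duplicate FASTA entry for {canonical} exon {exon_idx}")
        exdict[exon_idx] = seq.upper()

    records: dict[str, AlleleRecord] = {}
    template: dict[str, set[int]] = {}
    for canonical, exons in exons_by_allele.items():
        name = parse_allele_name(canonical)
        if canonical in records:
            raise DataError(f"duplicate allele {canonical}")
        records[canonical] = AlleleRecord(
            name=name,
            exons=exons,
            status=status_map.get(canonical, STATUS_OTHER),
            reconstructed_exons=recon_map.get(canonical, set()),
        )
        template.setdefault(name.locus, set()).update(exons)
    return AlleleLibrary(
        records=records,
        exon_template={k: tuple(sorted(v)) for k, v in template.items()},
    )


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment sequence identity between two nucleotide sequences.

    Identity is ``1 - d / max(len(a), len(b))`` where *d* is the global
    (Needleman-Wunsch) edit distance under unit mismatch/gap costs.  Symmetric,
    1.0 for identical sequences, and 0.75 for e.g. ``ACGT`` vs ``ACGA``.
    """
    if not a or not b:
        raise DataError("sequence_identity requires non-empty sequences")
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def concat_exons(rec: AlleleRecord, template: tuple[int, ...] | None = None) -> str:
    """Concatenate exon sequences in ascending exon order.

    When *template* is given, every template exon must be present (run
    :func:`reconstruct_missing_exons` first).
    """
    idxs = sorted(template) if template is not None else sorted(rec.exons)
    missing = [i for i in idxs if i not in rec.exons]
    if missing:
        raise DataError(f"allele {rec.name}: missing exon(s) {missing}")
    return "".join(rec.exons[i] for i in idxs)


def _donor_rank(rec: AlleleRecord) -> tuple:
    """Tie-break key: confirmed/common/well-documented first, then name."""
    return (0 if rec.status == STATUS_CWD else 1, str(rec.name))


def reconstruct_missing_exons(lib: AlleleLibrary) -> AlleleLibrary:
    """Fill missing exons from the closest same-locus donor allele.

    For each incomplete record, candidate donors are same-locus alleles whose
    *original* (database-provided) exons include the needed exon.  The donor
    with the highest :func:`sequence_identity` over the concatenation of
    exons originally present in both alleles is chosen; ties go first to
    confirmed and common, well-documented alleles, then to the smallest
    allele name.  Original exon sequences are never modified, and applying
    the operation twice is a no-op.
    """
    new_records: dict[str, AlleleRecord] = {}
    for key, rec in lib.records.items():
        template = set(lib.exon_template[rec.name.locus])
        missing = sorted(template - set(rec.exons))
        if not missing:
            new_records[key] = rec
            continue
        donors = [
            d for d in lib.by_locus(rec.name.locus) if str(d.name) != key
        ]
        # identity over exons originally present in both alleles
        scores: dict[str, float] = {}
        for d in donors:
            shared = sorted(rec.original_exons & d.original_exons)
            if shared:
                scores[str(d.name)] = sequence_identity(
                    "".join(rec.exons[i] for i in shared),
                    "".join(d.exons[i] for i in shared),
                )
        filled = dict(rec.exons)
        recon = set(rec.reconstructed_exons)
        for exon_idx in missing:
            candidates = [
                d
                for d in donors
                if exon_idx in d.original_exons and str(d.name) in scores
            ]
            if not candidates:
                raise DataError(
                    f"no donor allele at locus {rec.name.locus} provides exon "
                    f"{exon_idx} needed by {rec.name}"
                )
            best_score = max(scores[str(d.name)] for d in candidates)
            best = min(
                (d for d in candidates if scores[str(d.name)] == best_score),
                key=_donor_rank,
            )
            filled[exon_idx] = best.exons[exon_idx]
            recon.add(exon_idx)
        new_records[key] = AlleleRecord(
            name=rec.name, exons=filled, status=rec.status, reconstructed_exons=recon
        )
    return AlleleLibrary(
        records=new_records, exon_template=dict(lib.exon_template), version=lib.version
    )


# ---------------------------------------------------------------------------
# G groups


def _strip_prefix(canonical: str) -> str:
    return canonical.removeprefix("HLA-")


@dataclass
class GGroupTable:
    """Mapping from allele name to its G-group identifier.

    Alleles listed in the source table map to their group id; anything else
    falls back to its own name truncated to at most three fields (singleton
    semantics), so the mapping is total.  Keys are compared with the ``HLA-``
    prefix stripped, making tables and queries prefix-agnostic.
    """

    mapping: dict[str, str]

    def group_of(self, name: str | AlleleName) -> str:
        parsed = name if isinstance(name, AlleleName) else parse_allele_name(name)
        key = _strip_prefix(str(parsed))
        if key in self.mapping:
            return self.mapping[key]
        trunc = truncate_resolution(parsed, min(3, parsed.resolution))
        key3 = _strip_prefix(str(trunc))
        return self.mapping.get(key3, key3)

    def __len__(self) -> int:
        return len(self.mapping)


def load_g_groups(path: str | Path) -> GGroupTable:
    """Parse a G-group table in the ``hla_nom_g.txt`` dialect.

    Lines are ``locus*;allele1/allele2/...;GROUPG`` with ``#`` comments.  An
    empty third column marks a single ungrouped allele, which maps to its own
    (at most 3-field) name.  An allele listed in two groups is an error.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(";")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected ';'-delimited fields")
            locus_token = parts[0]
            members = [m for m in parts[1].split("/") if m]
            group = parts[2] if len(parts) > 2 else ""
            for member in members:
                full = parse_allele_name(locus_token + member)
                key = _strip_prefix(str(full))
                if group:
                    gid = _strip_prefix(locus_token + group)
                else:
                    gid = _strip_prefix(
                        str(truncate_resolution(full, min(3, full.resolution)))
                    )
                if key in mapping and mapping[key] != gid:
                    raise DataError(
                        f"{path}:{lineno}: allele {key} listed in two groups "
                        f"({mapping[key]} and {gid})"
                    )
                mapping[key] = gid
    return GGroupTable(mapping=mapping)


def save_g_groups(table: GGroupTable, path: str | Path) -> None:
    """Write a G-group table in the ``hla_nom_g.txt`` dialect."""
    by_group: dict[str, list[str]] = {}
    for member, gid in table.mapping.items():
        by_group.setdefault(gid, []).append(member)
    with open(path, "w") as fh:
        fh.write("# G-group ambiguity table\n")
        for gid in sorted(by_group):
            members = sorted(by_group[gid])
            locus_token = members[0].split("*")[0] + "*"
            rel = [m.split("*", 1)[1] for m in members]
            if len(members) == 1 and not gid.endswith("G"):
                fh.write(f"{locus_token};{rel[0]};\n")
            else:
                fh.write(f"{locus_token};{'/'.join(rel)};{gid.split('*', 1)[1]}\n")


def build_g_group_table(lib: AlleleLibrary) -> GGroupTable:
    """Derive the true G-group table of a library from its sequences.

    Alleles at the same locus with identical peptide-binding exon sequences
    form one group; a multi-allele group is named by the 3-field truncation of
    its lowest-numbered member followed by ``G``, singletons by their own
    (at most 3-field) name.
    """
    clusters: dict[tuple[str, str], list[AlleleRecord]] = {}
    for rec in lib.records.values():
        clusters.setdefault((rec.name.locus, rec.pb_sequence()), []).append(rec)
    mapping: dict[str, str] = {}
    for members in clusters.values():
        members = sorted(members, key=lambda r: r.name.numeric_key)
        lowest = members[0].name
        base = truncate_resolution(lowest, min(3, lowest.resolution))
        gid = _strip_prefix(str(base)) + ("G" if len(members) > 1 else "")
        for rec in members:
            mapping[_strip_prefix(str(rec.name))] = gid
    return GGroupTable(mapping=mapping)
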