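"""Projects, proteins, constructs, sequences, users and roles.

A *project* groups everything belonging to one structural-biology target:
proteins (each with a short safety *acronym*), constructs (sequence sets)
and the researchers who may read or write the project's data.  The acronym
is the case-sensitive identifier that appears on synchrotron safety sheets
and is embedded in every crystal sample name, so it is kept short and
strictly alphanumeric.

Sequences may be entered as amino acids or as nucleotides; nucleotide
sequences are immediately translated (reading frame 1, standard genetic
code) and the translation stored alongside.
"""

from __future__ import annotations

import io
import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO
from Bio.Data.CodonTable import TranslationError

from .errors import ConflictError, NotFoundError, PermissionDenied, ValidationError

# IUPAC alphabets.  Nucleotide includes ambiguity codes; amino-acid includes
# X (unknown), * (stop) and U/O (selenocysteine/pyrrolysine).
NUCLEOTIDE_LETTERS = set("ACGTURYSWKMBDHVN")
AMINO_ACID_LETTERS = set("ACDEFGHIKLMNPQRSTVWYXUO*")

_ACRONYM_RE = re.compile(r"^[A-Za-z0-9]+$")


@dataclass
class ValidationResult:
    """Severity-carrying result for soft checks (acronyms, sample names)."""

    severity: str  # "ok" | "warning" | "error"
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.severity == "ok"

    @property
    def is_error(self) -> bool:
        return self.severity == "error"


@dataclass
class User:
    username: str
    full_name: str = ""
    is_admin: bool = False
    is_shipper: bool = False
    # project_id -> "owner" | "member" | "guest"
    project_roles: dict[str, str] = field(default_factory=dict)


@dataclass
class Sequence:
    chain_label: str
    kind: str  # "nucleotide" | "amino_acid"
    residues: str
    translated: Optional[str] = None  # present iff kind == "nucleotide"


@dataclass
class Construct:
    id: str
    protein_id: str
    label: str
    sequences: list[Sequence] = field(default_factory=list)


@dataclass
class Protein:
    id: str
    project_id: str
    acronym: str
    full_name: str = ""
    description: str = ""
    construct_ids: list[str] = field(default_factory=list)


@dataclass
class Project:
    id: str
    name: str
    description: str
    owner: str
    protein_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# roles and permissions


def role_of(store, username: str, project_id: str) -> Optional[str]:
    """Return the caller's role on a project, or None."""
    user = store.users.get(username)
    if user is None:
        return None
    return user.project_roles.get(project_id)


def can_read(store, username: str, project_id: str) -> bool:
    user = store.users.get(username)
    if user is not None and user.is_admin:
        return True
    return role_of(store, username, project_id) in ("owner", "member", "guest")


def can_write(store, username: str, project_id: str) -> bool:
    """Owners and members may score, select, annotate; guests may not."""
    user = store.users.get(username)
    if user is not None and user.is_admin:
        return True
    return role_of(store, username, project_id) in ("owner", "member")


def require_write(store, username: str, project_id: str) -> None:
    if not can_write(store, username, project_id):
        raise PermissionDenied(
            f"user {username!r} has no write access to project {project_id!r}"
        )


# ---------------------------------------------------------------------------
# operations


def create_project(store, name: str, description: str, owner: str) -> Project:
    """Create a project; the owner gets the ``owner`` role.

    Names are descriptive, not keys: two projects may share a name and are
    told apart by their opaque ids.
    """
    if not name:
        raise ValidationError("project name must be non-empty")
    if owner not in store.users:
        raise NotFoundError(f"unknown user {owner!r}")
    project = Project(id=store.new_id("prj"), name=name,
                      description=description, owner=owner)
    store.projects[project.id] = project
    store.users[owner].project_roles[project.id] = "owner"
    return project


def validate_acronym(acronym: str, recommended_length: int = 5) -> ValidationResult:
    """Check a protein acronym.

    Empty or non-alphanumeric acronyms are errors; anything longer than the
    recommended five characters is flagged as a warning but accepted.
    """
    if not acronym:
        return ValidationResult("error", "acronym must be non-empty")
    if not _ACRONYM_RE.match(acronym):
        return ValidationResult(
            "error", f"acronym {acronym!r} contains special characters"
        )
    if len(acronym) > recommended_length:
        return ValidationResult(
            "warning",
            f"acronym {acronym!r} is {len(acronym)} characters; "
            f"at most {recommended_length} is recommended",
        )
    return ValidationResult("ok")


def add_protein(store, project: Project, acronym: str,
                full_name: str = "", description: str = "") -> Protein:
    """Add a protein to a project.

    The acronym must be unique within the project; different projects may
    reuse the same acronym.
    """
    result = validate_acronym(acronym)
    if result.is_error:
        raise ValidationError(result.message)
    for pid in project.protein_ids:
        if store.proteins[pid].acronym == acronym:
            raise ConflictError(
                f"acronym {acronym!r} already used in project {project.id!r}"
            )
    protein = Protein(id=store.new_id("prot"), project_id=project.id,
                      acronym=acronym, full_name=full_name,
                      description=description)
    store.proteins[protein.id] = protein
    project.protein_ids.append(protein.id)
    return protein


def add_construct(store, protein: Protein, label: str,
                  sequences: Iterable[tuple[str, str, str]]) -> Construct:
    """Add a construct (sequence set) to a protein.

    ``sequences`` is an iterable of ``(chain_label, kind, residues)``.
    At least one sequence is required; nucleotide sequences are translated
    on entry and stored with their translation.
    """
    seq_objs = [make_sequence(chain, kind, residues)
                for chain, kind, residues in sequences]
    if not seq_objs:
        raise ValidationError("a construct needs at least one sequence")
    construct = Construct(id=store.new_id("con"), protein_id=protein.id,
                          label=label, sequences=seq_objs)
    store.constructs[construct.id] = construct
    protein.construct_ids.append(construct.id)
    return construct


def make_sequence(chain_label: str, kind: str, residues: str) -> Sequence:
    """Validate residues against the IUPAC alphabet for ``kind`` and build
    a Sequence, translating nucleotides."""
    residues = residues.strip().upper()
    if not residues:
        raise ValidationError("sequence residues must be non-empty")
    if kind == "nucleotide":
        bad = set(residues) - NUCLEOTIDE_LETTERS
        if bad:
            raise ValidationError(
                f"illegal nucleotide letters: {''.join(sorted(bad))}"
            )
        return Sequence(chain_label=chain_label, kind=kind, residues=residues,
                        translated=translate_nucleotide(residues))
    elif kind == "amino_acid":
        bad = set(residues) - AMINO_ACID_LETTERS
        if bad:
            raise ValidationError(
                f"illegal amino-acid letters: {''.join(sorted(bad))}"
            )
        return Sequence(chain_label=chain_label, kind=kind, residues=residues)
    raise ValidationError(f"unknown sequence kind {kind!r}")


def translate_nucleotide(residues: str) -> str:
    """Translate a nucleotide sequence, reading frame 1, standard code.

    U is treated as T.  Ambiguity codes are translated where the codon is
    still uniquely decodable (e.g. GCN -> A) and yield 'X' otherwise.  Stop
    codons, internal or terminal, are kept as '*'.
    """
    residues = residues.strip().upper()
    if len(residues) % 3 != 0:
        raise ValidationError(
            f"sequence length {len(residues)} is not a multiple of 3"
        )
    bad = set(residues) - NUCLEOTIDE_LETTERS
    if bad:
        raise ValidationError(
            f"illegal nucleotide letters: {''.join(sorted(bad))}"
        )
    dna = residues.replace("U", "T")
    try:
        protein = str(Seq(dna).translate(table="Standard", to_stop=False))
    except TranslationError as exc:  # pragma: no cover - guarded above
        raise ValidationError(str(exc)) from exc
    # collapse two-letter ambiguity residues (B = D/N, Z = E/Q, J = I/L)
    # to X: a codon either decodes to one residue (or a stop) or is unknown
    return protein.translate(str.maketrans("BZJ", "XXX"))


def set_project_role(store, project: Project, username: str, role: str,
                     caller: str) -> Project:
    """Assign or remove a user's role on a project.

    Only the project owner or an admin may change roles.  ``role='none'``
    removes the user.  Each (user, project) pair holds exactly one role.
    """
    caller_user = store.users.get(caller)
    if caller_user is None:
        raise NotFoundError(f"unknown user {caller!r}")
    if not (caller_user.is_admin or project.owner == caller):
        raise PermissionDenied(
            f"user {caller!r} may not change roles on project {project.id!r}"
        )
    if role not in ("owner", "member", "guest", "none"):
        raise ValidationError(f"unknown role {role!r}")
    user = store.users.get(username)
    if user is None:
        raise NotFoundError(f"unknown user {username!r}")
    if role == "none":
        user.project_roles.pop(project.id, None)
    else:
        user.project_roles[project.id] = role
        if role == "owner":
            project.owner = username
    return project


# ---------------------------------------------------------------------------
# FASTA import / export


def sequences_to_fasta(store, construct: Construct) -> str:
    """Write a construct's sequences as FASTA, one record per chain.

    Headers are ``<construct label>|<chain label>|<kind>``; nucleotide
    records carry the raw nucleotides (the translation is derivable).
    """
    records = []
    for seq in construct.sequences:
        rec = SeqRecord(Seq(seq.residues),
                        id=f"{construct.label}|{seq.chain_label}|{seq.kind}",
                        description="")
        records.append(rec)
    buf = io.StringIO()
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()


def construct_from_fasta(store, protein: Protein, text: str,
                         default_kind: str = "amino_acid") -> Construct:
    """Import a construct from FASTA text.

    The header convention written by :func:`sequences_to_fasta` is parsed
    back; headers without the ``|`` convention fall back to the record id as
    chain label and ``default_kind``.
    """
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise ValidationError("FASTA input contains no records")
    label = None
    sequences = []
    for rec in records:
        parts = rec.id.split("|")
        if len(parts) == 3:
            rec_label, chain, kind = parts
            label = label or rec_label
        else:
            chain, kind = rec.id, default_kind
        sequences.append((chain, kind, str(rec.seq)))
    return add_construct(store, protein, label or protein.acronym, sequences)
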