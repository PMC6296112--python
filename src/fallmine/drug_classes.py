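"""ATC drug-class map for fall-risk pharmacovigilance.

Eight ATC classes drawn from the AGS 2015 Beers Criteria listing of
fall-risk medications (98 generics), plus two composite exposure
groups: CNS-active drugs (the union of opioids, benzodiazepines and
related drugs, hypnotics/sedatives, non-selective monoamine reuptake
inhibitors, and SSRIs) and calcium channel blockers (identical to the
C08 class, kept as a named group for drug-count items).

Names are matched case-insensitively after whitespace trimming; no
fuzzy matching.  A handful of aliases map common international
spellings onto the packaged entries.
"""

from __future__ import annotations

from .schema import CaseReport

# class_id -> (display name, {generic_name: ATC code})
CLASS_TABLE: dict[str, tuple[str, dict[str, str]]] = {
    "alpha_blockers": (
        "Alpha-adrenoreceptor antagonists",
        {
            "prazosin": "C02CA01",
            "doxazosin": "C02CA04",
            "urapidil": "C02CA06",
        },
    ),
    "diuretics": (
        "Sulfonamides, plain/Aryloxyacetic acid derivatives",
        {
            "frosemide": "C03CA01",
            "bumetanide": "C03CA02",
            "piretanide": "C03CA03",
            "torasemide": "C03CA04",
            "ethacrynic acid": "C03CC01",
        },
    ),
    "calcium_channel_blockers": (
        "Calcium channel blockers",
        {
            "amlodipine": "C08CA01",
            "felodipine": "C08CA02",
            "nicardipine": "C08CA04",
            "nifedipine": "C08CA05",
            "nisoldipine": "C08CA07",
            "nitrendipine": "C08CA08",
            "nilvadipine": "C08CA10",
            "manidipine": "C08CA11",
            "barnidipine": "C08CA12",
            "cilnidipine": "C08CA14",
            "benidipine": "C08CA15",
            "verapamil": "C08DA01",
            "diltiazem": "C08DB01",
            "bepridil": "C08EA02",
        },
    ),
    "opioids": (
        "Opioids",
        {
            "morphine": "N02AA01",
            "opium": "N02AA02",
            "oxycodone": "N02AA05",
            "dihydrocodeine": "N02AA08",
            "morphine, combinations": "N02AA51",
            "hydromorphone and naloxone": "N02AA53",
            "oxycodone and naloxone": "N02AA55",
            "oxycodone and naltrexone": "N02AA56",
            "dihydrocodeine, combinations": "N02AA58",
            "codeine, combinations excl. psycholeptics": "N02AA59",
            "codeine, combinations with psycholeptics": "N02AA79",
            "pethidine": "N02AB02",
            "fentanyl": "N02AB03",
            "pethidine, combinations excl. psycholeptics": "N02AB52",
            "pethidine, combinations with psycholeptics": "N02AB72",
            "methadone, combinations excl. psycholeptics": "N02AC52",
            "dextropropoxyphene, combinations excl. psycholeptics": "N02AC54",
            "dextropropoxyphene, combinations with psycholeptics": "N02AC74",
            "pentazocine": "N02AD01",
            "buprenorphine": "N02AE01",
            "butorphanol": "N02AF01",
            "morphine and antispasmodics": "N02AG01",
            "pethidine and antispasmodics": "N02AG03",
            "dihydrocodeine and paracetamol": "N02AJ01",
            "dihydrocodeine and acetylsalicylic acid": "N02AJ02",
            "dihydrocodeine and other non-opioid analgesics": "N02AJ03",
            "codeine and paracetamol": "N02AJ06",
            "codeine and acetylsalicylic acid": "N02AJ07",
            "codeine and ibuprofen": "N02AJ08",
            "codeine and other non-opioid analgesics": "N02AJ09",
            "tramadol and paracetamol": "N02AJ13",
            "tramadol and dexketoprofen": "N02AJ14",
            "tramadol and other non-opioid analgesics": "N02AJ15",
            "oxycodone and paracetamol": "N02AJ17",
            "oxycodone and acetylsalicylic acid": "N02AJ18",
            "oxycodone and ibuprofen": "N02AJ19",
            "tramadol": "N02AX02",
            "tapentadol": "N02AX06",
        },
    ),
    "benzodiazepines": (
        "Benzodiazepine derivatives/Benzodiazepine related drugs",
        {
            "flurazepam": "N05CD01",
            "nitrazepam": "N05CD02",
            "flunitrazepam": "N05CD03",
            "estazolam": "N05CD04",
            "triazoram": "N05CD05",
            "lormetazepam": "N05CD06",
            "midazolam": "N05CD08",
            "brotizolam": "N05CD09",
            "quazepam": "N05CD10",
            "zopiclone": "N05CF01",
            "zolpidem": "N05CF02",
            "eszopiclone": "N05CF04",
        },
    ),
    "hypnotics_sedatives": (
        "Barbiturates, plain, Aldehydes, Melatonin receptor agonists, "
        "and other hypnotics and sedatives",
        {
            "pentobarbital": "N05CA01",
            "amobarbital": "N05CA02",
            "barbital": "N05CA04",
            "secobarbital": "N05CA06",
            "thiopental": "N05CA19",
            "chloral hydrate": "N05CC01",
            "melatonin": "N05CH01",
            "ramelteon": "N05CH02",
            "bromisoval": "N05CM03",
            "scopolamine": "N05CM05",
            "triclofos": "N05CM07",
            "apronal": "N05CM12",
            "dexmedetomidine": "N05CM18",
        },
    ),
    "nsmri": (
        "Non-selective monoamine reuptake inhibitors",
        {
            "desipramine": "N06AA01",
            "imipramine": "N06AA02",
            "clomipramine": "N06AA04",
            "trimipramine": "N06AA06",
            "lefepramine": "N06AA07",
            "amitriptyline": "N06AA09",
            "nortriptyline": "N06AA10",
            "dosulepin": "N06AA16",
            "amoxapine": "N06AA17",
        },
    ),
    "ssri": (
        "Selective serotonin reuptake inhibitors",
        {
            "paroxetine": "N06AB05",
            "sertraline": "N06AB06",
            "fluvoxamine": "N06AB08",
            "escitalopram": "N06AB10",
        },
    ),
}

#: The eight primary classes, in the conventional reporting order.
CLASS_IDS: tuple[str, ...] = tuple(CLASS_TABLE)

#: The five classes whose union defines the CNS-active composite.
CNS_CLASS_IDS: tuple[str, ...] = (
    "opioids",
    "benzodiazepines",
    "hypnotics_sedatives",
    "nsmri",
    "ssri",
)

#: Composite exposure groups mapped to their member classes.
COMPOSITE_GROUPS: dict[str, tuple[str, ...]] = {
    "cns_active": CNS_CLASS_IDS,
    "calcium_channel_blockers": ("calcium_channel_blockers",),
}

#: Common international spellings accepted as input and resolved onto
#: the packaged entry (the packaged map itself is kept verbatim).
ALIASES: dict[str, str] = {
    "triazolam": "triazoram",
    "furosemide": "frosemide",
    "lofepramine": "lefepramine",
}

_NAME_TO_CLASS: dict[str, str] = {}
_NAME_TO_ATC: dict[str, str] = {}
for _cid, (_label, _members) in CLASS_TABLE.items():
    for _name, _atc in _members.items():
        _NAME_TO_CLASS[_name] = _cid
        _NAME_TO_ATC[_name] = _atc

N_LISTED_DRUGS = len(_NAME_TO_CLASS)  # 98 generics across the 8 classes


def display_name(class_id: str) -> str:
    if class_id == "cns_active":
        return "CNS-active drugs"
    return CLASS_TABLE[class_id][0]


def canonical_name(generic_name: str) -> str:
    """Trimmed, case-folded, alias-resolved generic name."""
    n = str(generic_name).strip().lower()
    return ALIASES.get(n, n)


def classify_drug(generic_name: str) -> frozenset[str]:
    """Class memberships of a generic name.

    Returns the drug's ATC class plus the ``cns_active`` composite when
    it belongs to one of the five CNS classes; empty set for unlisted
    drugs.
    """
    cid = _NAME_TO_CLASS.get(canonical_name(generic_name))
    if cid is None:
        return frozenset()
    if cid in CNS_CLASS_IDS:
        return frozenset({cid, "cns_active"})
    return frozenset({cid})


def atc_code(generic_name: str) -> str | None:
    return _NAME_TO_ATC.get(canonical_name(generic_name))


def group_members(group: str) -> frozenset[str]:
    """Canonical generic names belonging to a class or composite group."""
    if group in COMPOSITE_GROUPS:
        cids = COMPOSITE_GROUPS[group]
    elif group in CLASS_TABLE:
        cids = (group,)
    else:
        raise KeyError(f"unknown drug class or group: {group!r}")
    out: set[str] = set()
    for cid in cids:
        out.update(CLASS_TABLE[cid][1])
    return frozenset(out)


def report_classes(report: CaseReport) -> frozenset[str]:
    """All classes/groups touched by any drug in the report."""
    out: set[str] = set()
    for d in report.drugs:
        out |= classify_drug(d.generic_name)
    return frozenset(out)


def count_class_drugs(report: CaseReport, group: str) -> int:
    """Number of distinct listed substances in the report mapping to a group.

    Duplicate listings of one substance (e.g. suspected and concomitant)
    count once; all role codes are included.
    """
    members = group_members(group)
    return len({canonical_name(d.generic_name) for d in report.drugs} & members)
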