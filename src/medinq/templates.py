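"""Sentence templates for the synthetic inquiry generator.

Each template is a token pattern with typed entity slots (``{Treatment}``,
``{Condition}``, ``{Document}``, ``{Professional}``; a trailing digit, as in
``{Treatment2}``, requests a second distinct filler of the same type). Every
template carries the subcategory its instantiations are written to express,
and the packaged demo rule set labels noise-free instantiations back to that
subcategory — that closed loop is what makes the rule engine measurable
without the original proprietary corpus.

The three templates of Publication Request, Safety Data and Meeting Request
are modeled on a real three-sentence inquiry (documentation request, adverse
event question, liaison meeting request) and exercise the relation and
knowledgebase predicates; the Publication Request pattern intentionally also
satisfies the Safety Data rule so rule prioritization is routinely
exercised.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["Template", "TEMPLATES", "FALLBACK_TEMPLATES", "FILLERS",
           "LABEL_ORDER", "template_vocabulary"]

_SLOT = re.compile(r"\{([A-Za-z]+?)(\d?)\}")


@dataclass(frozen=True)
class Template:
    pattern: str
    label: str

    @property
    def slots(self) -> list[tuple[str, str]]:
        """(entity_type, slot_key) pairs in pattern order."""
        return [(m.group(1), m.group(1) + m.group(2))
                for m in _SLOT.finditer(self.pattern)]


#: Slot fillers in display form; they normalize onto the demo lexicon.
FILLERS: dict[str, list[str]] = {
    "Treatment": ["Product-A", "Product-B", "Curadol", "Zenatex",
                  "Mabrivan", "Oxitrel"],
    "Condition": ["allergies", "rash", "headache", "nausea", "migraine",
                  "hypertension", "diabetes", "asthma"],
    "Document": ["documentation", "publication", "poster", "article",
                 "brochure", "monograph"],
    "Professional": ["MSL", "medical advisor", "medical science liaison"],
}

_T: list[Template] = [
    # Scientific Exchange
    Template("Would like to have any documentation available on {Condition} of {Treatment}.", "Publication Request"),
    Template("Is there a publication available about {Treatment}?", "Publication Request"),
    Template("Could you send me a poster available on {Treatment}?", "Publication Request"),
    Template("I want {Professional} to meet me and discuss this further.", "Meeting Request"),
    Template("Can the {Professional} visit my clinic next week?", "Meeting Request"),
    Template("What is the mechanism of action of {Treatment}?", "Mechanism of Action"),
    Template("What is the half-life of {Treatment}?", "Pharmacokinetics"),
    Template("How is {Treatment} metabolized in patients?", "Pharmacokinetics"),
    # Safety
    Template("Are there any cases of {Condition} after taking {Treatment}?", "Safety Data"),
    Template("My patient developed {Condition} after taking {Treatment}.", "Safety Data"),
    Template("I would like to report a side effect of {Treatment}.", "Adverse Event Report"),
    Template("How do I report a side effect seen with {Treatment}?", "Adverse Event Report"),
    Template("Is {Treatment} contraindicated in patients with {Condition}?", "Contraindication"),
    Template("Is there an interaction between {Treatment} and {Treatment2}?", "Drug Interaction"),
    Template("Can {Treatment} be used during pregnancy?", "Pregnancy and Lactation"),
    Template("Is {Treatment} safe while breastfeeding?", "Pregnancy and Lactation"),
    # Dosage and Formulation
    Template("Is {Treatment} supplied as an oral formulation?", "Formulation"),
    Template("Does {Treatment} come in tablet form?", "Formulation"),
    Template("What is the recommended dose of {Treatment} for {Condition}?", "Dosage and Administration"),
    Template("How often should {Treatment} be administered?", "Dosage and Administration"),
    Template("How do I use the injection device for {Treatment}?", "Administration Device"),
    Template("How should {Treatment} be stored?", "Storage and Stability"),
    Template("Can {Treatment} be kept at room temperature?", "Storage and Stability"),
    # Clinical Evidence
    Template("How effective is {Treatment} in treating {Condition}?", "Efficacy"),
    Template("What is the response rate of {Treatment} in {Condition}?", "Efficacy"),
    Template("Is there any real world evidence on {Treatment} for {Condition}?", "Real world evidence"),
    Template("Which clinical trial evaluated {Treatment} in {Condition}?", "Clinical Trial Information"),
    Template("How does {Treatment} compare with {Treatment2} for {Condition}?", "Comparative Effectiveness"),
    # Product Support
    Template("Can I order samples of {Treatment}?", "Sample Request"),
    Template("I want to file a complaint about a damaged pack of {Treatment}.", "Product Complaint"),
    Template("Is {Treatment} out of stock in my region?", "Availability and Supply"),
    Template("When will {Treatment} be back in supply?", "Availability and Supply"),
    Template("What is the price of {Treatment}?", "Pricing and Reimbursement"),
    Template("Is {Treatment} covered by reimbursement?", "Pricing and Reimbursement"),
    Template("Can {Treatment} be prescribed off label for {Condition}?", "Off-label Use"),
    Template("Do you have a patient education brochure for {Treatment}?", "Patient Education"),
]

TEMPLATES: dict[str, list[Template]] = {}
for t in _T:
    TEMPLATES.setdefault(t.label, []).append(t)

#: Sentences no labeling rule matches; gold label is the fallback.
FALLBACK_TEMPLATES: list[str] = [
    "Thank you very much for your help.",
    "I hope you are doing well.",
    "This is a follow up to my previous message.",
    "Please let me know if you need more details.",
    "I look forward to hearing from you.",
]

#: Labels in descending intended frequency; the generator's Zipf ranks
#: follow this order.
LABEL_ORDER: list[str] = [
    "Safety Data",
    "Dosage and Administration",
    "Efficacy",
    "Publication Request",
    "Availability and Supply",
    "Drug Interaction",
    "Pricing and Reimbursement",
    "Meeting Request",
    "Formulation",
    "Storage and Stability",
    "Clinical Trial Information",
    "Adverse Event Report",
    "Contraindication",
    "Pregnancy and Lactation",
    "Real world evidence",
    "Mechanism of Action",
    "Sample Request",
    "Administration Device",
    "Pharmacokinetics",
    "Product Complaint",
    "Comparative Effectiveness",
    "Off-label Use",
    "Patient Education",
]

assert set(LABEL_ORDER) == set(TEMPLATES), "every label needs a template"


def template_vocabulary() -> set[str]:
    """Every lower-cased word that can appear in a rendered sentence."""
    vocab: set[str] = set()
    for tmpl in _T:
        text = _SLOT.sub(" ", tmpl.pattern)
        vocab.update(w.strip(".,?!").lower() for w in text.split())
    for text in FALLBACK_TEMPLATES:
        vocab.update(w.strip(".,?!").lower() for w in text.split())
    for fillers in FILLERS.values():
        for f in fillers:
            vocab.update(f.lower().split())
    vocab.discard("")
    return vocab
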