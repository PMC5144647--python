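"""Generate phonetic misspelling variants for drug keywords.

Runs the three-stage generator — distance-1 enumeration, phonetic filter,
frequency filter against a reference corpus — and prints the survivors.
"""

from drugchatter import CorpusFrequencyOracle, generate_misspellings, phonetic_code

# reference chatter in which some misspellings actually occur
reference = [
    "just took my adderal and i feel fine".split(),
    "ran out of seroquell again".split(),
    "adderal season is upon us".split(),
    "my doctor switched me to seroquel".split(),
]
oracle = CorpusFrequencyOracle(reference)

for drug in ("adderall", "seroquel", "xanax"):
    vs = generate_misspellings(drug, oracle=oracle, min_count=1)
    print(f"{drug} (code {phonetic_code(drug)}):")
    print(f"  stage1 distance-1 variants : {len(vs.stage1)}")
    print(f"  stage2 phonetically equal  : {len(vs.stage2)}")
    print(f"  stage3 frequency-attested  : {sorted(vs.stage3)}")

# stage1 counts hundreds of raw edits; the phonetic filter keeps the few
# that sound like the drug; stage3 keeps those people actually wrote in the
# reference corpus, e.g. the doubled-letter collapse "adderal".
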