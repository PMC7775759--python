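# Default binarization rules for the 35 WALS features with published
# temperature estimates.  The originally used scheme is not public; each
# mapping below is our own reconstruction from the WALS value inventories
# and is meant as an editable starting point, not as ground truth.
# Codes are WALS numeric value codes (as strings).  Any observed code not
# listed under present/absent/excluded is treated as an error.
features:
  "130A":
    label: "Hand and finger(s) identical"
    present: ["1"]          # identical
    absent: ["2"]           # different
  "8A":
    label: "Lateral consonants"
    present: ["2", "3", "4", "5"]   # any laterals
    absent: ["1"]                   # no laterals
  "92A":
    label: "Question particle"
    present: ["1", "2", "3", "4", "5"]  # particle in some position
    absent: ["6"]                       # no question particle
  "11A":
    label: "Front rounded vowels"
    present: ["2", "3", "4"]
    absent: ["1"]           # none
  "38A":
    label: "Indefinite marker"
    present: ["1", "2", "3"]    # indefinite word or affix
    absent: ["4", "5"]          # no indefinite article
  "37A":
    label: "Definite marker"
    present: ["1", "2", "3"]
    absent: ["4", "5"]
  "48A":
    label: "Adpositions"
    present: ["2", "3", "4", "5"]   # adpositions (any person marking)
    absent: ["1"]                   # no adpositions
  "100A":
    label: "Verbal person marking"
    present: ["2", "3", "4", "5", "6"]
    absent: ["1"]           # neutral (no person marking)
  "77A":
    label: "Grammatical evidentials"
    present: ["2", "3"]
    absent: ["1"]           # no grammatical evidentials
  "4A":
    label: "Voicing contrast"
    present: ["2", "3", "4"]
    absent: ["1"]           # no voicing contrast
  "143F":
    label: "Postverbal negative morpheme"
    present: ["1", "2", "3"]
    absent: ["4"]           # none
  "143E":
    label: "Preverbal negative morpheme"
    present: ["1", "2", "3"]
    absent: ["4"]
  "120A":
    label: "Zero copula for predicate nominals"
    present: ["2"]          # possible
    absent: ["1"]           # impossible
  "107A":
    label: "Passive construction"
    present: ["1"]
    absent: ["2"]
  "44A":
    label: "Gender in independent personal pronouns"
    present: ["1", "2", "3", "4", "5"]
    absent: ["6"]           # no gender distinctions
  "33A":
    label: "Plural"
    present: ["1", "2", "3", "4", "5", "6", "7", "8"]
    absent: ["9"]           # no plural
  "7A":
    label: "Glottalized consonants"
    present: ["2", "3", "4", "5", "6", "7", "8"]
    absent: ["1"]           # no glottalized consonants
  "6A":
    label: "Uvular consonants"
    present: ["2", "3", "4"]
    absent: ["1"]           # none
  "69A":
    label: "Tense-aspect inflection"
    present: ["1", "2", "3", "4"]   # tense-aspect affixes or tone
    absent: ["5"]                   # no tense-aspect inflection
  "73A":
    label: "Inflectional optative"
    present: ["1"]
    absent: ["2"]
  "26A":
    label: "Inflectional morphology"
    present: ["2", "3", "4", "5", "6"]
    absent: ["1"]           # little or no inflectional morphology
  "70A":
    label: "Morphological second-person imperative"
    present: ["1", "2", "3", "4"]
    absent: ["5"]           # no second-person imperative
  "119A":
    label: "Shared encoding of nominal and locational predication"
    present: ["2"]          # identical encoding
    absent: ["1"]           # different
  "57A":
    label: "Possessive affixes"
    present: ["1", "2", "3"]
    absent: ["4"]           # no possessive affixes
  "129A":
    label: "Hand and arm identical"
    present: ["1"]
    absent: ["2"]
  "13A":
    label: "Tone"
    present: ["2", "3"]
    absent: ["1"]           # no tones
  "91A":
    label: "Order of degree word and adjective is DegAdj"
    present: ["1"]          # DegAdj
    absent: ["2"]           # AdjDeg
    excluded: ["3"]         # no dominant order
  "87A":
    label: "Order of adjective and noun is AdjN"
    present: ["1"]
    absent: ["2"]
    excluded: ["3", "4"]
  "27A":
    label: "Productive reduplication"
    present: ["1", "2"]
    absent: ["3"]           # no productive reduplication
  "82A":
    label: "Order of subject and verb is SV"
    present: ["1"]
    absent: ["2"]
    excluded: ["3"]
  "9A":
    label: "Velar nasal"
    present: ["1", "2"]
    absent: ["3"]           # no velar nasal
  "89A":
    label: "Order of numeral and noun is NumN"
    present: ["1"]
    absent: ["2"]
    excluded: ["3", "4"]
  "83A":
    label: "Order of object and verb is OV"
    present: ["1"]
    absent: ["2"]
    excluded: ["3"]
  "86A":
    label: "Order of genitive and noun is GenN"
    present: ["1"]
    absent: ["2"]
    excluded: ["3"]
  "53A":
    label: "Ordinal numerals"
    present: ["2", "3", "4", "5", "6", "7", "8"]
    absent: ["1"]           # none
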