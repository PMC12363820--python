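{
  "_comment": "Synthetic reconstruction of a compact 35-question neurolinguistic bank. A handful of question texts are the well-known published examples (locations, time, dialogue, proper nouns, cultural references, technical terminology, journeys, visual scenes); the remainder were written to cover the same high-level categories (tactile sensations, visuospatial information, numerical information, planning, communication, abstract beliefs or values). Not the original study's list.",
  "questions": [
    {"qid": "q01", "text": "Does the input mention or describe a tactile sensation?", "tag": "tactile"},
    {"qid": "q02", "text": "Does the input describe a texture or surface quality?", "tag": "tactile"},
    {"qid": "q03", "text": "Does the input mention physical contact or touch between people or objects?", "tag": "tactile"},
    {"qid": "q04", "text": "Does the input describe a temperature or thermal sensation?", "tag": "tactile"},
    {"qid": "q05", "text": "Does the input describe a visual experience or scene?", "tag": "visuospatial"},
    {"qid": "q06", "text": "Does the input mention a specific location?", "tag": "visuospatial"},
    {"qid": "q07", "text": "Does the input describe a physical environment?", "tag": "visuospatial"},
    {"qid": "q08", "text": "Does the input describe the spatial arrangement or position of objects?", "tag": "visuospatial"},
    {"qid": "q09", "text": "Does the input describe movement through space?", "tag": "visuospatial"},
    {"qid": "q10", "text": "Does the input describe a journey?", "tag": "visuospatial"},
    {"qid": "q11", "text": "Does the input mention a color or visual appearance of something?", "tag": "visuospatial"},
    {"qid": "q12", "text": "Does the input contain a number or quantity?", "tag": "numerical"},
    {"qid": "q13", "text": "Does the input involve counting or measurement?", "tag": "numerical"},
    {"qid": "q14", "text": "Does the input mention time?", "tag": "numerical"},
    {"qid": "q15", "text": "Does the input mention a date, age, or duration?", "tag": "numerical"},
    {"qid": "q16", "text": "Does the input mention money or a financial transaction?", "tag": "numerical"},
    {"qid": "q17", "text": "Does the input describe a plan or intended future action?", "tag": "planning"},
    {"qid": "q18", "text": "Does the input describe a decision being made?", "tag": "planning"},
    {"qid": "q19", "text": "Does the input describe a goal or objective?", "tag": "planning"},
    {"qid": "q20", "text": "Does the input describe a problem being solved?", "tag": "planning"},
    {"qid": "q21", "text": "Does the input include dialogue?", "tag": "communication"},
    {"qid": "q22", "text": "Does the input describe a social interaction?", "tag": "communication"},
    {"qid": "q23", "text": "Does the input describe a relationship between people?", "tag": "communication"},
    {"qid": "q24", "text": "Does the input mention an act of speaking, telling, or explaining?", "tag": "communication"},
    {"qid": "q25", "text": "Does the input describe an emotional expression or reaction?", "tag": "communication"},
    {"qid": "q26", "text": "Does the input mention a family member or family relationship?", "tag": "communication"},
    {"qid": "q27", "text": "Does the input express a belief, value, or moral judgement?", "tag": "abstract"},
    {"qid": "q28", "text": "Does the input involve an abstract concept rather than a concrete object?", "tag": "abstract"},
    {"qid": "q29", "text": "Does the input mention religion or a spiritual practice?", "tag": "abstract"},
    {"qid": "q30", "text": "Does the input express uncertainty or doubt?", "tag": "abstract"},
    {"qid": "q31", "text": "Does the input describe a memory or recollection of the past?", "tag": "abstract"},
    {"qid": "q32", "text": "Does the input include technical or specialized terminology?", "tag": "abstract"},
    {"qid": "q33", "text": "Does the input contain a cultural reference?", "tag": "abstract"},
    {"qid": "q34", "text": "Does the input contain a proper noun?", "tag": "lexical"},
    {"qid": "q35", "text": "Does the input mention food, eating, or drinking?", "tag": "concrete"}
  ]
}
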