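{
  "title": "title",
  "abstract": "abstract",
  "summary": "abstract",
  "introduction": "introduction",
  "background": "introduction",
  "intro": "introduction",
  "methods": "methods",
  "method": "methods",
  "materials and methods": "methods",
  "material and methods": "methods",
  "patients and methods": "methods",
  "subjects and methods": "methods",
  "experimental procedures": "methods",
  "study design": "methods",
  "results": "results",
  "findings": "results",
  "results and discussion": "results",
  "discussion": "discussion",
  "comment": "discussion",
  "conclusion": "conclusion",
  "conclusions": "conclusion",
  "concluding remarks": "conclusion"
}
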