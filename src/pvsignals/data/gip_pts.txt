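Duodenal perforation
Duodenal ulcer perforation
Duodenal ulcer perforation, obstructive
Gastric perforation
Gastric ulcer perforation, obstructive
Gastrointestinal perforation
Ileal perforation
Ileal ulcer perforation
Intestinal perforation
Jejunal perforation
Jejunal ulcer perforation
Large intestine perforation
Oesophageal perforation
Peptic ulcer perforation
Rectal perforation
Small intestinal perforation
Oesophageal ulcer perforation
Large intestinal ulcer perforation
Small intestinal ulcer perforation
Intestinal ulcer perforation
Diverticular perforation
Gastrointestinal ulcer perforation
Upper gastrointestinal perforation
Lower gastrointestinal perforation
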