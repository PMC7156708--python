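# Safe-phrase library: short phrases with a high prior of NOT being PHI.
# Columns: polarity <TAB> category <TAB> description <TAB> pattern
# SAFE entries carry no category ("-"). Matches mark intersecting tokens INCLUDE.
SAFE	-	drug dosage with unit	(?i)\b\d+(?:\.\d+)?(?:\s?-\s?\d+(?:\.\d+)?)?\s?(?:mg|mcg|g|kg|ml|l|cc|units?|iu|meq|mmol|tabs?|tablets?|capsules?|puffs?|drops?|gtt|sprays?)\b
SAFE	-	physical measurement with unit	(?i)\b\d+(?:\.\d+)?\s?(?:cm|mm|m|in|ft|lbs?|lb|oz|bpm|mmhg|mg/dl|g/dl|mmol/l|meq/l|ml/hr|ml/min|l/min|cal|kcal)\b
SAFE	-	percentage value	\b\d+(?:\.\d+)?\s?%
SAFE	-	blood pressure reading in context	(?i)\b(?:bp|blood pressure)\s*(?:is|was|of)?\s*[:=]?\s*\d{2,3}\s?/\s?\d{2,3}\b
SAFE	-	heart rate in context	(?i)\b(?:hr|heart rate|pulse)\s*(?:is|was|of)?\s*[:=]?\s*\d{2,3}\b
SAFE	-	temperature in context	(?i)\btemp(?:erature)?\s*(?:is|was|of)?\s*[:=]?\s*\d{2,3}(?:\.\d)?\b
SAFE	-	oxygen saturation in context	(?i)\b(?:spo2|sao2|o2\s?sat(?:uration)?)\s*(?:is|was|of)?\s*[:=]?\s*\d{2,3}\b
SAFE	-	respiratory rate in context	(?i)\b(?:rr|respiratory rate|resp(?:irations)?)\s*(?:is|was|of)?\s*[:=]?\s*\d{1,2}\b
SAFE	-	common lab value in context	(?i)\b(?:wbc|rbc|hgb|hct|plt|platelets|sodium|potassium|na|k|cl|co2|bun|cr|creatinine|glucose|a1c|hba1c|inr|tsh|ldl|hdl|ast|alt|troponin)\s*(?:is|was|of)?\s*[:=]?\s*\d+(?:\.\d+)?\b
SAFE	-	clock time of day	\b\d{1,2}:\d{2}(?::\d{2})?\s?(?:am|pm|AM|PM)?\b
SAFE	-	duration with time unit	(?i)\b\d+(?:\s?-\s?\d+)?\s+(?:day|days|week|weeks|month|months|hour|hours|hr|hrs|minute|minutes|min)\b
SAFE	-	pain or clinical score out of ten	(?i)(?<![\d/.])\b\d{1,2}\s?/\s?10\b(?![\d/.])
SAFE	-	disease grade or stage	(?i)\b(?:grade|stage|class|type|level)\s+(?:\d{1,2}|i{1,3}v?|iv)\b
SAFE	-	ordinal day of course	(?i)\b(?:post-?op|hospital|treatment)\s+day\s+\d{1,2}\b
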