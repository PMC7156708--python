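# PHI pattern library: predictable PHI entities matched on raw note text.
# Columns: polarity <TAB> category <TAB> description <TAB> pattern
# A named group (?P<m>...) confines the claimed span to the PHI itself so
# that trigger context (e.g. "MRN:") is not redacted.
PHI	Email	email address	\b[A-Za-z0-9._%+-]+@[A-Za-z0-9.-]+\.[A-Za-z]{2,}\b
PHI	Patient_Social_Security_Number	social security number, dashed	\b\d{3}-\d{2}-\d{4}\b
PHI	Patient_Social_Security_Number	SSN with explicit label	(?i)\b(?:ssn|social security(?: number| no\.?)?)\s*[:#]?\s*(?P<m>\d{3}[- ]?\d{2}[- ]?\d{4})\b
PHI	Patient_Phone_Fax	US phone or fax number	\(?\b\d{3}\)?[-. ]\s?\d{3}[-. ]\d{4}\b
PHI	Date	numeric date with two separators	\b\d{1,2}[/-]\d{1,2}[/-]\d{2,4}\b
PHI	Date	ISO date	\b\d{4}-\d{2}-\d{2}\b
PHI	Date	month-name date, day first or last	(?i)\b(?:jan(?:uary)?|feb(?:ruary)?|mar(?:ch)?|apr(?:il)?|may|jun(?:e)?|jul(?:y)?|aug(?:ust)?|sep(?:t|tember)?|oct(?:ober)?|nov(?:ember)?|dec(?:ember)?)\.?\s+\d{1,2}(?:st|nd|rd|th)?(?:\s*,?\s+\d{4})?\b
PHI	Date	day before month name	(?i)\b\d{1,2}\s+(?:jan(?:uary)?|feb(?:ruary)?|mar(?:ch)?|apr(?:il)?|may|jun(?:e)?|jul(?:y)?|aug(?:ust)?|sep(?:t|tember)?|oct(?:ober)?|nov(?:ember)?|dec(?:ember)?)\.?(?:\s*,?\s+\d{4})?\b
PHI	Date	month name with year	(?i)\b(?:january|february|march|april|june|july|august|september|october|november|december)\.?,?\s+(?:19|20)\d{2}\b
PHI	URL_IP	web URL	(?i)\b(?:https?://|www\.)[^\s<>"]+
PHI	URL_IP	IPv4 address	\b\d{1,3}\.\d{1,3}\.\d{1,3}\.\d{1,3}\b
PHI	Patient_Medical_Record_Id	medical record number with label	(?i)\b(?:mrn|medical record(?: number| no\.?)?|med\.? rec\.?)\s*[:#]?\s*(?P<m>\d{5,12})\b
PHI	Patient_Account_Number	account number with label	(?i)\b(?:account|acct\.?)\s*(?:number|no\.?|#)?\s*[:#]?\s*(?P<m>\d{5,12})\b
PHI	Patient_Unique_ID	patient/visit identifier with label	(?i)\b(?:patient|pt\.?|unit|visit|encounter)\s*(?:id|identification)\s*(?:number|no\.?)?\s*[:#]?\s*(?P<m>[A-Za-z]?\d{4,12})\b
PHI	Provider_Certificate_or_License	license/DEA/NPI number with label	(?i)\b(?:license|lic\.?|dea|npi)\s*(?:number|no\.?|#)?\s*[:#]?\s*(?P<m>[A-Za-z]{0,3}\d{5,10})\b
PHI	Patient_Vehicle_or_Device_Id	device or vehicle serial with label	(?i)\b(?:serial|device|pacemaker|implant|vin)\s*(?:number|no\.?|#)?\s*[:#]?\s*(?P<m>[A-Za-z0-9]*\d[A-Za-z0-9-]{2,15})\b
PHI	Name	name following a salutation	\b(?:Mr|Mrs|Ms|Miss|Dr|Drs|Prof)\.?\s+(?P<m>[A-Z][A-Za-z'-]+(?:\s+[A-Z][A-Za-z'-]+)?)\b
PHI	Patient_Address	street address	(?i)\b\d{1,5}\s+[a-z]+(?:\s+[a-z]+)?\s+(?:street|st|avenue|ave|road|rd|drive|dr|lane|ln|boulevard|blvd|court|ct|place|pl|way|terrace|ter|circle|cir)\b\.?
PHI	Patient_Address	ZIP code after state abbreviation	\b[A-Z]{2},?\s+(?P<m>\d{5}(?:-\d{4})?)\b
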