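alcohol	organic chemical
ethanol	organic chemical
acetaldehyde	organic chemical
chlordiazepoxide	pharmacologic substance
chlordiazepoxide	organic chemical
librium	pharmacologic substance
diazepam	pharmacologic substance
diazepam	organic chemical
valium	pharmacologic substance
lorazepam	pharmacologic substance
oxazepam	pharmacologic substance
naltrexone	pharmacologic substance
disulfiram	pharmacologic substance
antabuse	pharmacologic substance
acamprosate	pharmacologic substance
benzodiazepine	pharmacologic substance
thiamine	pharmacologic substance
thiamine	vitamin
folate	vitamin
baclofen	pharmacologic substance
topiramate	pharmacologic substance
gabapentin	pharmacologic substance
clonidine	pharmacologic substance
sertraline	pharmacologic substance
buspirone	pharmacologic substance
alcoholism	mental or behavioral dysfunction
alcohol dependence	mental or behavioral dysfunction
alcohol abuse	mental or behavioral dysfunction
alcohol withdrawal	disease or syndrome
withdrawal	disease or syndrome
delirium tremens	disease or syndrome
anxiety	mental or behavioral dysfunction
depression	mental or behavioral dysfunction
insomnia	disease or syndrome
seizure	disease or syndrome
tremor	sign or symptom
nausea	sign or symptom
hallucination	sign or symptom
craving	sign or symptom
relapse	phenomenon or process
liver	body part
cirrhosis	disease or syndrome
hepatitis	disease or syndrome
pancreatitis	disease or syndrome
detox	therapeutic or preventive procedure
detoxification	therapeutic or preventive procedure
rehab	therapeutic or preventive procedure
rehabilitation	therapeutic or preventive procedure
therapy	therapeutic or preventive procedure
counseling	therapeutic or preventive procedure
abstinence	individual behavior
binge drinking	individual behavior
hangover	sign or symptom
blood alcohol	laboratory procedure
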