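# Digital-health related MeSH descriptors (26 terms).
Remote Sensing Technology
Remote Consultation
Remote Monitoring
Telerehabilitation
Digital Divide
Mobile Applications
Telemedicine
Internet
Smartphone
Algorithms
Electronic Health Records
Medical Informatics
Software
User-Computer Interface
Machine Learning
Artificial Intelligence
Text Messaging
Telephone
Cell Phone
Self-Management
Medical Informatics Applications
Wearable Electronic Devices
Information Dissemination
Videoconferencing
Digital Technology
Population Surveillance
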